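"""Shared fixtures: small synthetic runs generated once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from sholink.config import RunConfig
from sholink.pipeline import run_pipeline
from sholink.synth import ZERO_ERROR_MODEL


def _load(out_dir, name):
    return pd.read_csv(f"{out_dir}/{name}", dtype=str, keep_default_na=False)


class RunDir:
    """Convenience accessor over one pipeline run's interface files."""

    def __init__(self, cfg: RunConfig, results: dict):
        self.cfg = cfg
        self.results = results
        self.out = cfg.out_dir

    def read(self, name: str) -> pd.DataFrame:
        return _load(self.out, name)


@pytest.fixture(scope="session")
def zero_error_run(tmp_path_factory) -> RunDir:
    """Zero-error end-to-end run, n=600, window restricted to the report year."""
    cfg = RunConfig(
        seed=42,
        n_persons=600,
        out_dir=str(tmp_path_factory.mktemp("zero")),
        error_model=ZERO_ERROR_MODEL,
        years=(2015, 2019),
    )
    return RunDir(cfg, run_pipeline(cfg))


@pytest.fixture(scope="session")
def default_error_run(tmp_path_factory) -> RunDir:
    """Default-error end-to-end run, n=2000."""
    cfg = RunConfig(
        seed=99,
        n_persons=2000,
        out_dir=str(tmp_path_factory.mktemp("err")),
        years=(2015, 2019),
    )
    return RunDir(cfg, run_pipeline(cfg))
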