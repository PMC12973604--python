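"""End-to-end orchestration: simulate -> finder -> link -> classify ->
integrate -> report.

Each stage is a pure function of (input files, config, seed) and writes
its interface files under the configured output directory, so stages can
be re-run individually and fixed configs reproduce byte-identical
artifacts. Stage counts are appended to a line-delimited JSON log.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path

import pandas as pd

from . import classify as cls
from . import finder as fnd
from . import integrate as itg
from . import matching as mtc
from . import report as rpt
from .config import RunConfig
from .quality import Quality, Confidence
from .synth import SOURCE_FILES, export_sources, generate_population

__all__ = [
    "MissingInputError",
    "SchemaError",
    "run_pipeline",
    "stage_simulate",
    "stage_finder",
    "stage_link",
    "stage_classify",
    "stage_integrate",
    "stage_report",
]


class MissingInputError(FileNotFoundError):
    """An interface file required by a stage does not exist."""


class SchemaError(ValueError):
    """An interface file lacks required columns."""


def _read(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise MissingInputError(str(path))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    return df


def _log(out_dir: Path, stage: str, **payload) -> None:
    with (out_dir / "pipeline_log.jsonl").open("a") as fh:
        fh.write(json.dumps({"stage": stage, **payload}, sort_keys=True) + "\n")


def stage_simulate(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    population = generate_population(
        cfg.n_persons, seed=cfg.seed, overlap=cfg.overlap, birth_year_range=cfg.birth_year_range
    )
    export_sources(
        population, out, error_model=cfg.error_model, event_model=cfg.event_model,
        years=cfg.years, seed=cfg.seed,
    )
    counts = {
        "persons": len(population),
        "in_sho": sum(p.in_sho for p in population),
        "in_medicare": sum(p.in_medicare for p in population),
        "in_both": sum(p.in_sho and p.in_medicare for p in population),
    }
    _log(out, "simulate", **counts)
    return counts


def stage_finder(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    licensing = _read(out / SOURCE_FILES["licensing"], ["sho_row_id"] + fnd.SIX_REQUIRED)
    drivers = _read(out / SOURCE_FILES["crash_driverlevel"], ["sho_row_id"] + fnd.SIX_REQUIRED)
    ff = fnd.build_finder_file(
        licensing, drivers,
        birth_year_range=cfg.birth_year_range,
        death_cutoff=date(cfg.death_cutoff_year, 1, 1),
    )
    fnd.finder_frame(ff).to_csv(out / "finder_file.csv", index=False, lineterminator="\n")
    ff.counts_frame.to_csv(out / "finder_stages.csv", index=False, lineterminator="\n")
    ff.rejects.to_csv(out / "finder_rejects.csv", index=False, lineterminator="\n")
    counts = {"stages": ff.stage_counts, "rejects": len(ff.rejects)}
    _log(out, "finder", **counts)
    return counts


def stage_link(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    finder = _read(out / "finder_file.csv", ["sho_id"] + fnd.SIX_REQUIRED)
    mbsf = _read(out / SOURCE_FILES["mbsf"], ["bene_id"] + fnd.SIX_REQUIRED)
    bene = mbsf.sort_values("year").drop_duplicates("bene_id", keep="last")
    a = mtc.prepare_identifiers(finder)
    b = mtc.prepare_identifiers(bene)
    pairs = mtc.block_candidates(a, b)
    scored = mtc.score_candidates(
        a, b, pairs, nickname_table=cfg.error_model.nickname_table, rules=cfg.name_rules
    )
    scored.to_csv(out / "candidates.csv", index=False, lineterminator="\n")
    counts = {"finder": len(finder), "beneficiaries": len(bene), "candidate_pairs": len(scored)}
    _log(out, "link", **counts)
    return counts


def stage_classify(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    scored = _read(out / "candidates.csv", ["sho_id", "bene_id"] + cls.QUALITY_COLUMNS)
    for col in cls.QUALITY_COLUMNS:
        scored[col] = scored[col].astype(int)
    scored = cls.add_confidence(scored, cfg.pattern_table)
    resolved, dropped = cls.resolve_one_to_many(scored)
    dropped.to_csv(out / "resolution_log.csv", index=False, lineterminator="\n")

    finder = _read(out / "finder_file.csv", ["sho_id", "sho_row_id"])
    report = cls.strategy_report(resolved, n_final_cohort=len(finder))
    report.to_csv(out / "strategy_report.csv", index=False, lineterminator="\n")

    accepted = cls.apply_strategy(resolved, cfg.strategy)
    xw = cls.build_crosswalk(accepted)
    xw = xw.merge(finder[["sho_id", "sho_row_id"]], on="sho_id", how="left")
    labeled = xw.copy()
    for col in cls.QUALITY_COLUMNS:
        labeled[col] = labeled[col].map(lambda v: Quality(int(v)).label)
    labeled["confidence"] = labeled["confidence"].map(lambda v: Confidence(int(v)).label)
    cols = ["sho_id", "sho_row_id", "bene_id", "bid"] + cls.QUALITY_COLUMNS + ["confidence", "cardinality"]
    labeled[cols].to_csv(out / "accepted_crosswalk.csv", index=False, lineterminator="\n")
    counts = {
        "resolved": len(resolved),
        "dropped_in_resolution": len(dropped),
        "accepted": len(accepted),
        "strategy": cfg.strategy,
    }
    _log(out, "classify", **counts)
    return counts


def stage_integrate(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    xw = _read(out / "accepted_crosswalk.csv", ["sho_id", "sho_row_id", "bene_id", "bid"])
    panel, audit = itg.build_panel(
        crosswalk=xw,
        licensing=_read(out / SOURCE_FILES["licensing"], ["sho_row_id", "phase", "phase_start", "phase_end"]),
        crash_crashlevel=_read(out / SOURCE_FILES["crash_crashlevel"], ["crash_id", "crash_date"]),
        crash_driverlevel=_read(out / SOURCE_FILES["crash_driverlevel"], ["sho_row_id", "crash_id"]),
        citations=_read(out / SOURCE_FILES["citations"], ["sho_row_id", "citation_date"]),
        suspensions=_read(out / SOURCE_FILES["suspensions"], ["sho_row_id", "suspension_start"]),
        mbsf=_read(out / SOURCE_FILES["mbsf"], ["bene_id", "year"]),
        window=(cfg.report_year, cfg.report_year),
    )
    panel.to_csv(out / "person_month.csv", index=False, lineterminator="\n")
    audit.to_csv(out / "unlinked_audit.csv", index=False, lineterminator="\n")
    counts = {"panel_rows": len(panel), "audit_rows": len(audit)}
    _log(out, "integrate", **counts)
    return counts


def stage_report(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    panel = _read(out / "person_month.csv", ["bid", "year", "month", "ffs_covered"])
    panel["year"] = panel["year"].astype(int)
    panel["month"] = panel["month"].astype(int)
    for col in ("licensed_any_day", "ffs_covered", "ma_month"):
        panel[col] = panel[col].map({"True": True, "False": False}).astype(bool)
    for col in ("n_crashes", "n_citations", "n_suspensions"):
        panel[col] = panel[col].astype(int)

    xw = _read(out / "accepted_crosswalk.csv", ["bid", "sho_row_id", "bene_id"])
    mbsf = _read(out / SOURCE_FILES["mbsf"], ["bene_id", "year"])
    bene = mbsf.sort_values("year").drop_duplicates("bene_id", keep="last")
    persons = xw.merge(bene, on="bene_id", how="left")

    cohort = rpt.select_cohort(panel, persons, cfg.report_year)

    lic = _read(out / SOURCE_FILES["licensing"], ["sho_row_id", "phase_start", "phase_end"])
    lic = lic.merge(xw[["bid", "sho_row_id"]], on="sho_row_id")
    lic["phase_start"] = pd.to_datetime(lic["phase_start"], errors="coerce")
    lic["phase_end"] = pd.to_datetime(lic["phase_end"], errors="coerce")

    summary = rpt.summarize(cohort, panel, persons, lic, cfg.report_year)
    if summary.rows is not None:
        summary.rows.to_csv(out / "cohort_summary.csv", index=False, lineterminator="\n")
    counts = {"cohort_n": summary.n, "year": cfg.report_year}
    _log(out, "report", **counts)
    return counts


_STAGES = [
    ("simulate", stage_simulate),
    ("finder", stage_finder),
    ("link", stage_link),
    ("classify", stage_classify),
    ("integrate", stage_integrate),
    ("report", stage_report),
]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages in order; returns the per-stage count summaries."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = out / "pipeline_log.jsonl"
    if log.exists():
        log.unlink()
    results = {}
    for name, fn in _STAGES:
        results[name] = fn(cfg)
    return results
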