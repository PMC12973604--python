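"""Precision/recall of an accepted crosswalk against synthetic ground truth.

The denominator is the set of *linkable* truth pairs: those whose registry
record survived to the finder file and whose beneficiary record appears in
the beneficiary source. Accepted pairs outside that set count as false
positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["LinkageScore", "score_against_truth"]


@dataclass(frozen=True)
class LinkageScore:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 1.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 1.0


def score_against_truth(
    accepted: pd.DataFrame,
    finder: pd.DataFrame,
    truth: pd.DataFrame,
    bene_ids: pd.Series | set,
) -> LinkageScore:
    """Score accepted (sho_id, bene_id) pairs against the truth crosswalk.

    ``finder`` supplies the sho_id <-> sho_row_id mapping; ``bene_ids`` is
    the set of beneficiary ids present in the beneficiary source.
    """
    id_map = finder.set_index("sho_id")["sho_row_id"]
    accepted_pairs = {
        (id_map.get(s), b) for s, b in zip(accepted["sho_id"], accepted["bene_id"])
    }
    present_rows = set(finder["sho_row_id"])
    present_benes = set(bene_ids)
    truth_pairs = {
        (r, b)
        for r, b in zip(truth["sho_row_id"], truth["bene_id"])
        if r in present_rows and b in present_benes
    }
    tp = len(accepted_pairs & truth_pairs)
    return LinkageScore(
        true_positives=tp,
        false_positives=len(accepted_pairs) - tp,
        false_negatives=len(truth_pairs) - tp,
    )
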