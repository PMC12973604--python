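"""Overall match confidence, duplicate resolution, and acceptance strategies.

Confidence is assigned from the pattern of the four category qualities by a
first-match-wins pattern table. The default table is:

* ``Strong``  -- at least three of the four categories rate High;
* ``Fair``    -- name and age both rate Medium or better;
* ``Weak``    -- everything else.

This table honors the two anchor patterns (all-High -> Strong; High name
with Medium sex/age/residence -> Fair) and guarantees that every pair
accepted by Strategy 5 is Strong or Fair. It ships as editable
configuration for studies that need a different banding.

Five acceptance strategies are provided:

1. accept Strong and Fair, reject all Weak;
2. accept pairs with 3-4 High categories;
3. name High/Medium AND age High;
4. name High/Medium AND age High/Medium;
5. (name High/Medium AND age High) OR (name, sex, residence all High).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .quality import CATEGORIES, CategoryQualities, Confidence, Quality

__all__ = [
    "ConfidencePattern",
    "ConfidencePatternTable",
    "DEFAULT_PATTERN_TABLE",
    "assign_confidence",
    "add_confidence",
    "resolve_one_to_many",
    "STRATEGY_LABELS",
    "strategy_mask",
    "apply_strategy",
    "strategy_report",
    "percent",
    "build_crosswalk",
]

QUALITY_COLUMNS = ["q_name", "q_sex", "q_age", "q_residence"]


@dataclass(frozen=True)
class ConfidencePattern:
    """One row of the pattern table: per-category minimum qualities plus an
    optional minimum count of High categories. All stated conditions must
    hold for the pattern to match."""

    min_quality: dict = field(default_factory=dict)  # category -> Quality
    min_high_count: int | None = None

    def matches(self, q: CategoryQualities) -> bool:
        for cat, minimum in self.min_quality.items():
            if getattr(q, cat) < minimum:
                return False
        if self.min_high_count is not None and q.high_count < self.min_high_count:
            return False
        return True

    def to_dict(self) -> dict:
        d = {cat: Quality(v).label for cat, v in self.min_quality.items()}
        if self.min_high_count is not None:
            d["min_high_count"] = self.min_high_count
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConfidencePattern":
        d = dict(d)
        mhc = d.pop("min_high_count", None)
        unknown = set(d) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in confidence pattern: {sorted(unknown)}")
        return cls(
            min_quality={cat: Quality.from_label(v) for cat, v in d.items()},
            min_high_count=mhc,
        )


@dataclass(frozen=True)
class ConfidencePatternTable:
    """Ordered (pattern, confidence) rules; the first matching pattern wins
    and anything unmatched falls through to Weak."""

    rules: tuple = ()

    def assign(self, q: CategoryQualities) -> Confidence:
        for pattern, confidence in self.rules:
            if pattern.matches(q):
                return confidence
        return Confidence.WEAK

    def assign_frame(self, df: pd.DataFrame) -> np.ndarray:
        """Vectorized confidence for a frame with integer q_* columns."""
        n = len(df)
        out = np.full(n, int(Confidence.WEAK))
        decided = np.zeros(n, dtype=bool)
        qcols = {cat: df[f"q_{cat}"].to_numpy() for cat in CATEGORIES}
        high_count = sum((qcols[cat] == int(Quality.HIGH)).astype(int) for cat in CATEGORIES)
        for pattern, confidence in self.rules:
            mask = ~decided
            for cat, minimum in pattern.min_quality.items():
                mask &= qcols[cat] >= int(minimum)
            if pattern.min_high_count is not None:
                mask &= high_count >= pattern.min_high_count
            out[mask] = int(confidence)
            decided |= mask
        return out

    def to_list(self) -> list:
        return [
            {"pattern": p.to_dict(), "confidence": c.label} for p, c in self.rules
        ]

    @classmethod
    def from_list(cls, rows: list) -> "ConfidencePatternTable":
        rules = tuple(
            (ConfidencePattern.from_dict(r["pattern"]), Confidence.from_label(r["confidence"]))
            for r in rows
        )
        return cls(rules=rules)


DEFAULT_PATTERN_TABLE = ConfidencePatternTable(
    rules=(
        (ConfidencePattern(min_high_count=3), Confidence.STRONG),
        (
            ConfidencePattern(min_quality={"name": Quality.MEDIUM, "age": Quality.MEDIUM}),
            Confidence.FAIR,
        ),
    )
)


def assign_confidence(
    qualities: CategoryQualities,
    pattern_table: ConfidencePatternTable = DEFAULT_PATTERN_TABLE,
) -> Confidence:
    """Overall confidence of one pair under the (default) pattern table."""
    return pattern_table.assign(qualities)


def add_confidence(
    candidates: pd.DataFrame,
    pattern_table: ConfidencePatternTable = DEFAULT_PATTERN_TABLE,
) -> pd.DataFrame:
    """Return candidates with an integer ``confidence`` column appended."""
    out = candidates.copy()
    out["confidence"] = pattern_table.assign_frame(candidates)
    return out


def resolve_one_to_many(candidates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enforce at most one beneficiary per registry id and vice versa.

    For each contested id the maximal candidate under the ranking
    (confidence, count of High categories, name quality, age quality) is
    kept; exact ties go to the lexicographically smaller bene_id, then
    sho_id. Returns (kept, dropped); kept rows carry a ``cardinality``
    column: ``one_to_one`` where the pair was uncontested on both sides,
    ``one_to_many_resolved`` otherwise.
    """
    if candidates.empty:
        kept = candidates.copy()
        kept["cardinality"] = pd.Series(dtype=str)
        return kept, candidates.copy()
    df = candidates.copy()
    high_count = sum((df[c] == int(Quality.HIGH)).astype(int) for c in QUALITY_COLUMNS)
    order = df.assign(_hc=high_count).sort_values(
        ["confidence", "_hc", "q_name", "q_age", "bene_id", "sho_id"],
        ascending=[False, False, False, False, True, True],
        kind="mergesort",
    )
    used_sho: set = set()
    used_bene: set = set()
    keep_idx = []
    for idx, sho, bene in zip(order.index, order["sho_id"], order["bene_id"]):
        if sho in used_sho or bene in used_bene:
            continue
        used_sho.add(sho)
        used_bene.add(bene)
        keep_idx.append(idx)
    kept = df.loc[keep_idx].sort_values(["sho_id", "bene_id"])
    dropped = df.drop(index=keep_idx).sort_values(["sho_id", "bene_id"])
    contested_sho = set(df.loc[df["sho_id"].duplicated(keep=False), "sho_id"])
    contested_bene = set(df.loc[df["bene_id"].duplicated(keep=False), "bene_id"])
    contested = kept["sho_id"].isin(contested_sho) | kept["bene_id"].isin(contested_bene)
    kept = kept.assign(
        cardinality=np.where(contested, "one_to_many_resolved", "one_to_one")
    ).reset_index(drop=True)
    return kept, dropped.reset_index(drop=True)


STRATEGY_LABELS = {
    1: "Accept Strong + Fair, reject all Weak",
    2: "Accept matches with 3-4 Highs",
    3: "Name (High/Medium) AND Age High",
    4: "Name (High/Medium) AND Age (High/Medium)",
    5: "[Name (High/Medium) AND Age High] OR 3 Highs in Name, Sex, and Residence",
}

_H, _M = int(Quality.HIGH), int(Quality.MEDIUM)


def strategy_mask(candidates: pd.DataFrame, strategy_id: int) -> np.ndarray:
    """Boolean acceptance mask for one strategy over a scored/classified frame."""
    name = candidates["q_name"].to_numpy()
    sex = candidates["q_sex"].to_numpy()
    age = candidates["q_age"].to_numpy()
    res = candidates["q_residence"].to_numpy()
    if strategy_id == 1:
        return candidates["confidence"].to_numpy() >= int(Confidence.FAIR)
    if strategy_id == 2:
        high_count = sum((q == _H).astype(int) for q in (name, sex, age, res))
        return high_count >= 3
    if strategy_id == 3:
        return (name >= _M) & (age == _H)
    if strategy_id == 4:
        return (name >= _M) & (age >= _M)
    if strategy_id == 5:
        return ((name >= _M) & (age == _H)) | ((name == _H) & (sex == _H) & (res == _H))
    raise ValueError(f"unknown strategy id: {strategy_id}")


def apply_strategy(candidates: pd.DataFrame, strategy_id: int) -> pd.DataFrame:
    """Accepted subset of (already classified, already resolved) candidates."""
    return candidates.loc[strategy_mask(candidates, strategy_id)].reset_index(drop=True)


def percent(count: int, denominator: int) -> float:
    """count / denominator * 100, rounded to two decimals half away from zero.

    Reproduces every printed cohort percentage from its printed numerator
    and denominator. A zero denominator reports 0.00.
    """
    if denominator == 0:
        return 0.0
    pct = Decimal(int(count)) / Decimal(int(denominator)) * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def strategy_report(candidates: pd.DataFrame, n_final_cohort: int) -> pd.DataFrame:
    """Accepted counts and percent-of-final-cohort for all five strategies."""
    rows = []
    for sid in sorted(STRATEGY_LABELS):
        accepted = int(strategy_mask(candidates, sid).sum())
        rows.append(
            {
                "strategy": sid,
                "criteria": STRATEGY_LABELS[sid],
                "accepted": accepted,
                "pct_of_final": percent(accepted, n_final_cohort),
            }
        )
    return pd.DataFrame(rows)


def build_crosswalk(accepted: pd.DataFrame) -> pd.DataFrame:
    """Assign the post-linkage person key (BID) to accepted pairs.

    BIDs are sequential opaque keys issued in sorted sho_id order, so the
    crosswalk is a pure function of the accepted set.
    """
    out = accepted.sort_values("sho_id").reset_index(drop=True).copy()
    out.insert(2, "bid", [f"B{i:08d}" for i in range(1, len(out) + 1)])
    return out
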