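"""Annual cohort selection and characterization.

The report-year cohort is the set of linked individuals aged 65+ at the
start of the year whose every alive month in the year was fee-for-service
covered ("FFS throughout the year or until death"). The summary mirrors a
standard administrative-cohort table: age bands and quartiles, sex,
race/ethnicity, in-year death/crash/citation flags, licensed-all-year, and
ever-diagnosed chronic-condition flags. All percentages use the shared
two-decimal half-away-from-zero rounding rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .classify import percent
from .integrate import licensed_every_day

__all__ = ["CohortSummary", "select_cohort", "summarize"]

AGE_BANDS = [(65, 69), (70, 74), (75, 79), (80, 84), (85, None)]

RACE_LEVELS = [
    "American Indian/Alaskan Native",
    "Asian/Pacific Islander",
    "Black (or African American)",
    "Hispanic",
    "Non-Hispanic White",
    "Other",
    "Unknown",
]


@dataclass
class CohortSummary:
    """Counts and percents for one report year; ``rows`` is the printable table."""

    n: int
    year: int
    median_age: float
    q1_age: float
    q3_age: float
    rows: pd.DataFrame = field(repr=False, default=None)


def select_cohort(panel: pd.DataFrame, persons: pd.DataFrame, year: int) -> pd.Series:
    """BIDs aged >= 65 at the start of ``year`` with every alive month in
    the year fee-for-service covered (and at least one alive month).

    ``persons`` must carry bid and the beneficiary-side birth_date.
    """
    birth = pd.to_datetime(persons["birth_date"], errors="coerce")
    year_start = pd.Timestamp(date(year, 1, 1))
    b65 = birth + pd.DateOffset(years=65)
    aged = persons.loc[b65 <= year_start, "bid"]

    in_year = panel.loc[panel["year"] == year]
    by_bid = in_year.groupby("bid")["ffs_covered"].agg(["all", "size"])
    ffs_throughout = by_bid.index[(by_bid["all"]) & (by_bid["size"] > 0)]
    return pd.Series(sorted(set(aged) & set(ffs_throughout)), name="bid", dtype=str)


def _age_on(birth: pd.Series, ref: pd.Series) -> np.ndarray:
    """Completed years between two datetime series."""
    age = ref.dt.year - birth.dt.year
    before_birthday = (ref.dt.month < birth.dt.month) | (
        (ref.dt.month == birth.dt.month) & (ref.dt.day < birth.dt.day)
    )
    return (age - before_birthday.astype(int)).to_numpy()


def summarize(
    cohort: pd.Series,
    panel: pd.DataFrame,
    persons: pd.DataFrame,
    licensing: pd.DataFrame,
    year: int,
    condition_columns: list[str] | None = None,
) -> CohortSummary:
    """Characterize the cohort for the report year.

    ``persons`` carries bid plus beneficiary attributes (birth/death dates,
    sex, race_ethnicity, cond_* onset columns); ``licensing`` carries
    bid-keyed phase intervals (datetime columns). Age is measured on
    December 31 of the report year or at death. "Licensed all year"
    requires a valid phase on every day of the calendar year.
    """
    members = persons.loc[persons["bid"].isin(set(cohort))].copy()
    n = len(members)
    rows: list[dict] = []

    def add(label: str, count: int, denominator: int | None = n):
        rows.append(
            {
                "characteristic": label,
                "count": int(count),
                "percent": percent(int(count), denominator if denominator else 0),
            }
        )

    if n == 0:
        empty = pd.DataFrame(columns=["characteristic", "count", "percent"])
        summary = CohortSummary(n=0, year=year, median_age=float("nan"),
                                q1_age=float("nan"), q3_age=float("nan"), rows=empty)
        return summary

    birth = pd.to_datetime(members["birth_date"], errors="coerce")
    death = pd.to_datetime(members["death_date"], errors="coerce")
    year_end = pd.Timestamp(date(year, 12, 31))
    ref = death.where(death.notna() & (death <= year_end), year_end)
    ages = _age_on(birth, ref)

    q1, med, q3 = np.percentile(ages, [25, 50, 75])
    rows.append({"characteristic": "N", "count": n, "percent": 100.0})
    for lo, hi in AGE_BANDS:
        mask = ages >= lo if hi is None else (ages >= lo) & (ages <= hi)
        label = f">= {lo}" if hi is None else f"{lo}-{hi}"
        add(f"Age {label}", mask.sum())
    add("Female", members["sex"].eq("F").sum())
    for level in RACE_LEVELS:
        add(f"Race/Ethnicity {level}", members["race_ethnicity"].eq(level).sum())
    died_in_year = death.notna() & (death.dt.year == year)
    add("Died during the year", died_in_year.sum())

    in_year = panel.loc[(panel["year"] == year) & panel["bid"].isin(set(cohort))]
    by_bid = in_year.groupby("bid")[["n_crashes", "n_citations"]].sum()
    add("Crashed", (by_bid["n_crashes"] > 0).sum())
    add("Received a citation", (by_bid["n_citations"] > 0).sum())

    lic = licensing.loc[licensing["bid"].isin(set(cohort))]
    covered = licensed_every_day(
        lic, pd.Timestamp(date(year, 1, 1)), pd.Timestamp(date(year + 1, 1, 1))
    )
    add("Licensed all year", int(covered.reindex(members["bid"], fill_value=False).sum()))

    if condition_columns is None:
        condition_columns = [c for c in members.columns if c.startswith("cond_")]
    for col in condition_columns:
        onset = pd.to_datetime(members[col], errors="coerce")
        add(f"Chronic condition {col.removeprefix('cond_')}", (onset <= year_end).sum())

    return CohortSummary(
        n=n, year=year, median_age=float(med), q1_age=float(q1), q3_age=float(q3),
        rows=pd.DataFrame(rows),
    )
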