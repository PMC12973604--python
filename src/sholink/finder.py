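"""Eligibility cascade producing the finder file submitted for linkage.

The registry-side sources are reduced to one identifier record per
individual and passed through three audited filters:

1. *eligible* -- present in the licensing or crash data, born within the
   configured birth-year window (default 1900-1954, the cohort that is
   age-eligible for Medicare during the data years), and not dead before
   the death-cutoff year (default: died in or before 2006 excluded);
2. *complete* -- non-missing first name, last name, sex, date of birth,
   state, and ZIP (a missing death date is allowed);
3. *post-65 survival* -- individuals who died strictly before their 65th
   birthday are excluded (a Feb-29 birthday rolls to Mar-1).

Each stage appends to an audit trail of (stage label, surviving count).
Records with unparseable dates are routed to a rejects report, never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date

import pandas as pd

__all__ = ["FinderFile", "load_sho_records", "filter_eligible", "filter_complete",
           "exclude_pre65_deaths", "assign_sho_ids", "build_finder_file"]

SIX_REQUIRED = ["first_name", "last_name", "sex", "birth_date", "state", "zip"]


@dataclass
class FinderFile:
    """Surviving identifier records plus the stage-count audit trail."""

    records: pd.DataFrame
    stage_counts: list = dc_field(default_factory=list)
    rejects: pd.DataFrame = dc_field(
        default_factory=lambda: pd.DataFrame(columns=["sho_row_id", "field", "value", "reason"])
    )

    def log_stage(self, label: str) -> "FinderFile":
        self.stage_counts.append((label, len(self.records)))
        return self

    @property
    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_counts, columns=["stage", "count"]).assign(
            order=range(1, len(self.stage_counts) + 1)
        )[["order", "stage", "count"]]


def _parse_date_column(df: pd.DataFrame, col: str) -> tuple[pd.Series, pd.DataFrame]:
    """ISO date parse; returns (parsed, rejects-for-this-column)."""
    raw = df[col].fillna("").astype(str).str.strip()
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = raw.ne("") & parsed.isna()
    rejects = pd.DataFrame(
        {
            "sho_row_id": df.loc[bad, "sho_row_id"],
            "field": col,
            "value": raw[bad],
            "reason": "unparseable date",
        }
    )
    return parsed, rejects


def load_sho_records(licensing: pd.DataFrame, crash_drivers: pd.DataFrame) -> FinderFile:
    """Collapse registry sources to one identifier record per individual.

    ``appears_in`` records which of the two qualifying datasets the person
    has a record in. Identifier fields are taken from the licensing record
    where present, otherwise from the crash driver-level record.
    Date-validation failures go to the rejects report and the offending
    records are withheld from the cascade.
    """
    ident_cols = ["sho_row_id"] + SIX_REQUIRED + ["death_date"]
    lic = licensing[ident_cols].drop_duplicates("sho_row_id").assign(_src="licensing")
    crash = crash_drivers[ident_cols].drop_duplicates("sho_row_id").assign(_src="crash")
    combined = pd.concat([lic, crash], ignore_index=True)
    appears = combined.groupby("sho_row_id")["_src"].agg(lambda s: ";".join(sorted(set(s))))
    records = (
        combined.drop_duplicates("sho_row_id", keep="first")
        .drop(columns="_src")
        .merge(appears.rename("appears_in"), left_on="sho_row_id", right_index=True)
        .sort_values("sho_row_id", ignore_index=True)
    )
    reject_parts = []
    for col in ("birth_date", "death_date"):
        parsed, rejects = _parse_date_column(records, col)
        records["_" + col] = parsed
        reject_parts.append(rejects)
    rejects = pd.concat(reject_parts, ignore_index=True)
    bad_ids = set(rejects["sho_row_id"])
    ff = FinderFile(
        records=records.loc[~records["sho_row_id"].isin(bad_ids)].reset_index(drop=True),
        rejects=rejects,
    )
    return ff.log_stage("registry individuals (licensing or crash)")


def filter_eligible(
    ff: FinderFile,
    birth_year_range: tuple[int, int] = (1900, 1954),
    death_cutoff: date = date(2007, 1, 1),
) -> FinderFile:
    """Keep records in the birth-year window that did not die before the
    cutoff (death in or before ``death_cutoff.year - 1`` excludes; a missing
    death date is retained)."""
    r = ff.records
    by = r["_birth_date"].dt.year
    keep = (
        r["appears_in"].ne("")
        & by.ge(birth_year_range[0])
        & by.le(birth_year_range[1])
        & (r["_death_date"].isna() | (r["_death_date"] >= pd.Timestamp(death_cutoff)))
    )
    ff.records = r.loc[keep].reset_index(drop=True)
    return ff.log_stage(
        f"born {birth_year_range[0]}-{birth_year_range[1]}, "
        f"not dead before {death_cutoff.isoformat()}"
    )


def filter_complete(ff: FinderFile) -> FinderFile:
    """Keep records with all six linkage identifiers non-missing (death
    date excepted)."""
    r = ff.records
    keep = pd.Series(True, index=r.index)
    for col in SIX_REQUIRED:
        keep &= r[col].fillna("").astype(str).str.strip().ne("")
    ff.records = r.loc[keep].reset_index(drop=True)
    return ff.log_stage("non-missing name, sex, birth date, state, ZIP")


def _birthday_65(born: pd.Series) -> pd.Series:
    """65th birthday for a datetime series; Feb-29 rolls to Mar-1."""
    out = []
    for ts in born:
        d = ts.date()
        try:
            out.append(pd.Timestamp(d.replace(year=d.year + 65)))
        except ValueError:
            out.append(pd.Timestamp(date(d.year + 65, 3, 1)))
    return pd.Series(out, index=born.index)


def exclude_pre65_deaths(ff: FinderFile) -> FinderFile:
    """Drop records that died strictly before their 65th birthday; dying on
    the birthday (Medicare age eligibility starts) retains the record."""
    r = ff.records
    if len(r):
        b65 = _birthday_65(r["_birth_date"])
        keep = r["_death_date"].isna() | (r["_death_date"] >= b65)
    else:
        keep = pd.Series(dtype=bool)
    ff.records = r.loc[keep].reset_index(drop=True)
    return ff.log_stage("survived to 65th birthday")


def assign_sho_ids(ff: FinderFile) -> FinderFile:
    """Issue a fresh registry linkage id per surviving individual."""
    r = ff.records.sort_values("sho_row_id", ignore_index=True)
    r.insert(0, "sho_id", [f"S{i:07d}" for i in range(1, len(r) + 1)])
    ff.records = r
    return ff.log_stage("final individuals for linkage")


def build_finder_file(
    licensing: pd.DataFrame,
    crash_drivers: pd.DataFrame,
    birth_year_range: tuple[int, int] = (1900, 1954),
    death_cutoff: date = date(2007, 1, 1),
) -> FinderFile:
    """Run the full cascade: load -> eligible -> complete -> post-65 -> ids."""
    ff = load_sho_records(licensing, crash_drivers)
    ff = filter_eligible(ff, birth_year_range, death_cutoff)
    ff = filter_complete(ff)
    ff = exclude_pre65_deaths(ff)
    return assign_sho_ids(ff)


def finder_frame(ff: FinderFile) -> pd.DataFrame:
    """Plain-column view for writing finder_file.csv."""
    cols = ["sho_id", "sho_row_id"] + SIX_REQUIRED + ["death_date", "appears_in"]
    return ff.records[cols].copy()
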