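"""Join linked sources on the common person key and build person-month panels.

After linkage every dataset can be keyed by BID (the post-linkage person
key). The panel has one row per linked person per month, from the window
start through the month of death (the death month itself generates a row),
with:

* ``licensed_any_day`` -- a license phase interval covers at least one day
  of the month (phase intervals are half-open ``[start, end)``);
* ``ffs_covered`` / ``ma_month`` -- monthly coverage from the beneficiary
  summary (fee-for-service = Parts A+B without a capitated Part C plan);
* event counts (crashes by crash date via the crash-level record,
  citations, suspensions by start date).

Events for registry individuals who were not linked, or dated outside the
panel (after death or outside the window), are retained in an audit frame
rather than silently dropped.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

__all__ = ["license_status_on", "ever_diagnosed", "build_panel", "licensed_every_day"]


def license_status_on(phases: pd.DataFrame, bid: str, on: date) -> str | None:
    """Phase held on a given day, or None.

    ``phases`` columns: bid, phase, phase_start, phase_end (datetime-like;
    missing end = open interval). Intervals are half-open [start, end): the
    start day is licensed, the end day is not.
    """
    ts = pd.Timestamp(on)
    mine = phases.loc[phases["bid"] == bid]
    for _, row in mine.iterrows():
        start, end = row["phase_start"], row["phase_end"]
        if pd.isna(start):
            continue
        if start <= ts and (pd.isna(end) or ts < end):
            return str(row["phase"])
    return None


def ever_diagnosed(onsets: pd.DataFrame, bid: str, condition: str, as_of: date) -> bool:
    """True iff the condition's earliest-diagnosis date is on or before ``as_of``."""
    col = condition if condition in onsets.columns else f"cond_{condition}"
    if col not in onsets.columns:
        raise KeyError(f"unknown condition: {condition}")
    row = onsets.loc[onsets["bid"] == bid]
    if row.empty:
        return False
    onset = pd.to_datetime(row.iloc[0][col], errors="coerce")
    return bool(pd.notna(onset) and onset <= pd.Timestamp(as_of))


def _month_index(window: tuple[int, int]) -> pd.DatetimeIndex:
    return pd.date_range(
        start=f"{window[0]}-01-01", end=f"{window[1]}-12-01", freq="MS"
    )


def licensed_every_day(phases: pd.DataFrame, start: pd.Timestamp, end_exclusive: pd.Timestamp) -> pd.Series:
    """Per-bid flag: the union of phase intervals covers every day of
    [start, end_exclusive)."""
    out = {}
    for bid, grp in phases.groupby("bid"):
        ivs = []
        for _, row in grp.iterrows():
            s = row["phase_start"]
            e = row["phase_end"] if pd.notna(row["phase_end"]) else end_exclusive
            if pd.isna(s) or e <= start or s >= end_exclusive:
                continue
            ivs.append((max(s, start), min(e, end_exclusive)))
        ivs.sort()
        covered_until = start
        for s, e in ivs:
            if s > covered_until:
                break
            covered_until = max(covered_until, e)
        out[bid] = covered_until >= end_exclusive
    return pd.Series(out, dtype=bool)


def build_panel(
    crosswalk: pd.DataFrame,
    licensing: pd.DataFrame,
    crash_crashlevel: pd.DataFrame,
    crash_driverlevel: pd.DataFrame,
    citations: pd.DataFrame,
    suspensions: pd.DataFrame,
    mbsf: pd.DataFrame,
    window: tuple[int, int] = (2019, 2019),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the person-month panel; returns (panel, audit).

    ``crosswalk`` must carry bid, sho_id, sho_row_id, bene_id. Dates in the
    source frames are ISO strings. The panel holds one row per bid per
    month alive within the calendar window; a person's death month is the
    last row. Months with no enrollment record have both coverage flags
    False.
    """
    months = _month_index(window)
    xw = crosswalk[["bid", "sho_row_id", "bene_id"]].copy()

    # person attributes from the beneficiary side (one row per bene)
    bene = (
        mbsf.sort_values("year")
        .drop_duplicates("bene_id", keep="last")[["bene_id", "birth_date", "death_date"]]
        .copy()
    )
    bene["death_ts"] = pd.to_datetime(bene["death_date"], errors="coerce")
    persons = xw.merge(bene, on="bene_id", how="left")

    # cartesian person x month, truncated at death month
    panel = persons[["bid", "death_ts"]].merge(pd.DataFrame({"month_start": months}), how="cross")
    death_month_end = persons[["bid", "death_ts"]].set_index("bid")["death_ts"].dt.to_period("M").dt.to_timestamp()
    panel = panel.merge(death_month_end.rename("death_month"), left_on="bid", right_index=True, how="left")
    panel = panel.loc[panel["death_month"].isna() | (panel["month_start"] <= panel["death_month"])]
    panel = panel.drop(columns=["death_ts"]).reset_index(drop=True)
    panel["year"] = panel["month_start"].dt.year
    panel["month"] = panel["month_start"].dt.month
    panel["alive"] = True

    # coverage flags from the monthly indicators
    cov_cols = [f"cov_{mo:02d}" for mo in range(1, 13)]
    cov_long = mbsf.melt(
        id_vars=["bene_id", "year"], value_vars=cov_cols, var_name="cov_col", value_name="cov"
    )
    cov_long["month"] = cov_long["cov_col"].str[4:].astype(int)
    cov_long["year"] = cov_long["year"].astype(int)
    cov_long = cov_long.merge(xw[["bid", "bene_id"]], on="bene_id")
    panel = panel.merge(
        cov_long[["bid", "year", "month", "cov"]], on=["bid", "year", "month"], how="left"
    )
    panel["ffs_covered"] = panel["cov"].eq("FFS").fillna(False)
    panel["ma_month"] = panel["cov"].eq("MA").fillna(False)
    panel = panel.drop(columns="cov")

    # licensed_any_day: phase interval overlaps [month_start, next_month)
    lic = licensing.merge(xw[["bid", "sho_row_id"]], on="sho_row_id")
    lic["phase_start"] = pd.to_datetime(lic["phase_start"], errors="coerce")
    lic["phase_end"] = pd.to_datetime(lic["phase_end"], errors="coerce")
    month_end = panel["month_start"] + pd.offsets.MonthBegin(1)
    panel["licensed_any_day"] = False
    if len(lic):
        key = panel[["bid", "month_start"]].copy()
        key["month_end"] = month_end
        j = key.merge(lic[["bid", "phase_start", "phase_end"]], on="bid", how="left")
        overlap = (
            j["phase_start"].notna()
            & (j["phase_start"] < j["month_end"])
            & (j["phase_end"].isna() | (j["phase_end"] > j["month_start"]))
        )
        any_overlap = overlap.groupby([j["bid"], j["month_start"]]).any()
        panel["licensed_any_day"] = (
            panel.set_index(["bid", "month_start"]).index.map(any_overlap).fillna(False).to_numpy()
        )

    # event counts per month
    audits = []

    def _monthly_counts(events: pd.DataFrame, date_col: str, out_col: str, label: str):
        nonlocal panel
        ev = events.merge(xw[["bid", "sho_row_id"]], on="sho_row_id", how="left")
        unlinked = ev.loc[ev["bid"].isna()]
        if len(unlinked):
            audits.append(
                unlinked.assign(reason="unlinked individual", source=label)[
                    ["source", "sho_row_id", date_col, "reason"]
                ].rename(columns={date_col: "event_date"})
            )
        ev = ev.loc[ev["bid"].notna()].copy()
        ts = pd.to_datetime(ev[date_col], errors="coerce")
        ev["year"] = ts.dt.year
        ev["month"] = ts.dt.month
        counts = ev.groupby(["bid", "year", "month"]).size().rename(out_col).reset_index()
        panel = panel.merge(counts, on=["bid", "year", "month"], how="left")
        panel[out_col] = panel[out_col].fillna(0).astype(int)
        # events that found no panel row (outside window or after death)
        merged = counts.merge(panel[["bid", "year", "month"]], on=["bid", "year", "month"], how="left", indicator=True)
        lost = merged.loc[merged["_merge"] == "left_only"]
        if len(lost):
            audits.append(
                pd.DataFrame(
                    {
                        "source": label,
                        "sho_row_id": "",
                        "event_date": lost["year"].astype(str) + "-" + lost["month"].astype(str).str.zfill(2),
                        "reason": "event outside panel (window/death bounds)",
                    }
                )
            )

    crashes = crash_driverlevel[["sho_row_id", "crash_id"]].merge(
        crash_crashlevel[["crash_id", "crash_date"]], on="crash_id"
    )
    _monthly_counts(crashes, "crash_date", "n_crashes", "crash")
    _monthly_counts(citations, "citation_date", "n_citations", "citation")
    _monthly_counts(suspensions, "suspension_start", "n_suspensions", "suspension")

    audit = (
        pd.concat(audits, ignore_index=True)
        if audits
        else pd.DataFrame(columns=["source", "sho_row_id", "event_date", "reason"])
    )
    panel = panel[
        ["bid", "year", "month", "licensed_any_day", "ffs_covered", "ma_month",
         "n_crashes", "n_citations", "n_suspensions", "alive"]
    ].sort_values(["bid", "year", "month"], ignore_index=True)
    return panel, audit
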