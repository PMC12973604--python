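"""Synthetic administrative sources with a known ground-truth crosswalk.

This module emulates the two sources the linkage consumes: a state
traffic-safety registry (licensing phases, citations, suspensions, and
crash records at crash level and driver level) and a Medicare-style annual
beneficiary summary file with monthly coverage indicators and
chronic-condition first-diagnosis dates. A configurable fraction of the
population appears in both sources, and each source's view of a person's
identifiers is independently corrupted through an explicit error model
(nickname variants, single-character typos, birth-date component errors
and day/month swaps, sex miscodes, stale residence, missing fields), so
every downstream stage can be validated against known truth.

Default event rates are calibrated to a 2019 fee-for-service cohort of
older adults: 2.47 crash involvements and 2.13 citations per 100
person-years, 63.14% licensed every day of the year, ~3.66% annual
mortality after 65, and a ~37% capitated (Medicare Advantage) plan share.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import names as pools

__all__ = [
    "TruePerson",
    "ErrorModel",
    "EventModel",
    "DEFAULT_ERROR_MODEL",
    "ZERO_ERROR_MODEL",
    "DEFAULT_EVENT_MODEL",
    "generate_population",
    "corrupt_identifiers",
    "generate_events",
    "export_sources",
    "SOURCE_FILES",
]

_EPOCH = date(1900, 1, 1)
_HORIZON = date(2024, 12, 31)


def _from_ordinal_days(days: int) -> date:
    return _EPOCH + timedelta(days=int(days))


@dataclass
class TruePerson:
    """Ground-truth individual feeding both synthetic sources."""

    person_uid: str
    first_name: str
    last_name: str
    sex: str  # "F" | "M"
    birth_date: date
    death_date: date | None
    residence_history: list  # [(state, zip, start_date)], sorted by start
    race_ethnicity: str
    in_sho: bool
    in_medicare: bool

    @property
    def age65_date(self) -> date:
        return _shift_years(self.birth_date, 65)


def _shift_years(d: date, years: int) -> date:
    """Same month/day ``years`` later; Feb-29 rolls forward to Mar-1."""
    try:
        return d.replace(year=d.year + years)
    except ValueError:
        return date(d.year + years, 3, 1)


@dataclass(frozen=True)
class ErrorModel:
    """Per-field, per-source-record identifier corruption probabilities."""

    p_nickname: float = 0.08
    p_typo: float = 0.01
    p_dob_component_error: float = 0.02
    p_dob_daymonth_swap: float = 0.005
    p_sex_miscode: float = 0.005
    p_zip_stale: float = 0.25
    p_missing_field: float = 0.0005
    nickname_table: dict = field(default_factory=lambda: dict(pools.NICKNAMES))

    def __post_init__(self):
        for f in (
            "p_nickname", "p_typo", "p_dob_component_error", "p_dob_daymonth_swap",
            "p_sex_miscode", "p_zip_stale", "p_missing_field",
        ):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")

    def to_dict(self) -> dict:
        return {
            "p_nickname": self.p_nickname,
            "p_typo": self.p_typo,
            "p_dob_component_error": self.p_dob_component_error,
            "p_dob_daymonth_swap": self.p_dob_daymonth_swap,
            "p_sex_miscode": self.p_sex_miscode,
            "p_zip_stale": self.p_zip_stale,
            "p_missing_field": self.p_missing_field,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorModel":
        return cls(**d)


DEFAULT_ERROR_MODEL = ErrorModel()
ZERO_ERROR_MODEL = ErrorModel(
    p_nickname=0.0, p_typo=0.0, p_dob_component_error=0.0, p_dob_daymonth_swap=0.0,
    p_sex_miscode=0.0, p_zip_stale=0.0, p_missing_field=0.0,
)


@dataclass(frozen=True)
class EventModel:
    """Event-process and coverage parameters (rates per person-year)."""

    crash_rate: float = 0.0247
    citation_rate: float = 0.0213
    suspension_rate: float = 0.010
    p_licensed_full_year: float = 0.6314
    chronic_condition_prevalences: dict = field(default_factory=lambda: dict(pools.CONDITIONS))
    p_ffs_month: float = 0.63
    p_crash_injury: float = 0.25
    p_two_driver_crash: float = 0.15

    def __post_init__(self):
        for f in ("crash_rate", "citation_rate", "suspension_rate"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        for f in ("p_licensed_full_year", "p_ffs_month", "p_crash_injury", "p_two_driver_crash"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        for cond, p in self.chronic_condition_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {cond} must be in [0, 1], got {p}")

    def to_dict(self) -> dict:
        return {
            "crash_rate": self.crash_rate,
            "citation_rate": self.citation_rate,
            "suspension_rate": self.suspension_rate,
            "p_licensed_full_year": self.p_licensed_full_year,
            "chronic_condition_prevalences": dict(self.chronic_condition_prevalences),
            "p_ffs_month": self.p_ffs_month,
            "p_crash_injury": self.p_crash_injury,
            "p_two_driver_crash": self.p_two_driver_crash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventModel":
        return cls(**d)


DEFAULT_EVENT_MODEL = EventModel()

#: first year of the synthetic traffic-safety registry's licensing data
_REGISTRY_ERA_START = 2004

#: annual post-65 mortality hazard: 1 - exp(-h) = 0.0366
DEATH_HAZARD_65 = 0.037287
#: lifetime probability of dying before 65 (uniform over ages 20-65)
P_DEATH_PRE65 = 0.05


def generate_population(
    n: int,
    seed: int,
    overlap: float = 0.85,
    birth_year_range: tuple[int, int] = (1900, 1954),
    death_hazard: float = DEATH_HAZARD_65,
    p_death_pre65: float = P_DEATH_PRE65,
) -> list[TruePerson]:
    """Draw ``n`` ground-truth persons; deterministic for a fixed seed.

    ``overlap`` is the probability a person is present in both sources; the
    remainder is split evenly between registry-only and Medicare-only.
    Given names and surnames are sampled with Zipf-like weights so that
    common names are common, as in real registries. Mortality is a constant
    annual hazard after the 65th birthday (default calibrated so ~3.66% of
    an annual cohort dies in-year) plus a small pre-65 component.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must be in [0, 1], got {overlap}")
    rng = np.random.default_rng(seed)

    sex = np.where(rng.random(n) < 0.52, "F", "M")
    male_idx = rng.choice(
        len(pools.MALE_FIRST), size=n, p=pools.zipf_weights(len(pools.MALE_FIRST), 0.8)
    )
    female_idx = rng.choice(
        len(pools.FEMALE_FIRST), size=n, p=pools.zipf_weights(len(pools.FEMALE_FIRST), 0.8)
    )
    last_idx = rng.choice(
        len(pools.SURNAMES), size=n, p=pools.zipf_weights(len(pools.SURNAMES), 0.9)
    )

    y0, y1 = birth_year_range
    start = (date(y0, 1, 1) - _EPOCH).days
    end = (date(y1, 12, 31) - _EPOCH).days
    birth_days = rng.integers(start, end + 1, size=n)

    u = rng.random(n)
    both = u < overlap
    sho_only = (~both) & (u < overlap + (1 - overlap) / 2)

    race_labels = [r for r, _ in pools.RACE_ETHNICITY]
    race_p = np.array([p for _, p in pools.RACE_ETHNICITY])
    race = rng.choice(len(race_labels), size=n, p=race_p / race_p.sum())

    dies_pre65 = rng.random(n) < p_death_pre65
    pre65_age_days = rng.uniform(20 * 365.25, 65 * 365.25, size=n)
    post65_wait_years = rng.exponential(1.0 / death_hazard, size=n) if death_hazard > 0 else np.full(n, np.inf)

    n_res = rng.choice([1, 2, 3], size=n, p=[0.6, 0.3, 0.1])
    horizon_days = (_HORIZON - _EPOCH).days

    persons: list[TruePerson] = []
    for i in range(n):
        bdate = _from_ordinal_days(birth_days[i])
        if dies_pre65[i]:
            ddate: date | None = _from_ordinal_days(birth_days[i] + int(pre65_age_days[i]))
        else:
            d65 = _shift_years(bdate, 65)
            dd = (d65 - _EPOCH).days + int(post65_wait_years[i] * 365.25)
            ddate = _from_ordinal_days(dd) if dd <= horizon_days else None

        k = int(n_res[i])
        first_start = birth_days[i] + int(18 * 365.25)
        starts = [first_start]
        if k > 1:
            lo = max(first_start + 365, (date(1975, 1, 1) - _EPOCH).days)
            extra = sorted(rng.integers(lo, horizon_days - 365, size=k - 1).tolist())
            starts += extra
        res = []
        state = "NJ"
        for j, s in enumerate(starts):
            if j > 0 and rng.random() < 0.12:
                state = pools.OUT_OF_STATE[rng.integers(0, len(pools.OUT_OF_STATE))]
            zips = pools.STATE_ZIPS[state]
            res.append((state, zips[rng.integers(0, len(zips))], _from_ordinal_days(s)))

        persons.append(
            TruePerson(
                person_uid=f"P{i:07d}",
                first_name=(
                    pools.MALE_FIRST[male_idx[i]] if sex[i] == "M"
                    else pools.FEMALE_FIRST[female_idx[i]]
                ),
                last_name=pools.SURNAMES[last_idx[i]],
                sex=str(sex[i]),
                birth_date=bdate,
                death_date=ddate,
                residence_history=res,
                race_ethnicity=race_labels[race[i]],
                in_sho=bool(both[i] or sho_only[i]),
                in_medicare=bool(both[i] or (~both[i] and not sho_only[i])),
            )
        )
    return persons


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _apply_typo(name: str, rng: np.random.Generator) -> str:
    """One uniformly chosen substitution, deletion, or transposition."""
    if len(name) < 2:
        return name
    op = rng.integers(0, 3)
    if op == 0:  # substitution
        i = int(rng.integers(0, len(name)))
        c = _LETTERS[rng.integers(0, 26)]
        if name[i].isupper():
            c = c.upper()
        return name[:i] + c + name[i + 1 :]
    if op == 1:  # deletion
        i = int(rng.integers(0, len(name)))
        return name[:i] + name[i + 1 :]
    i = int(rng.integers(0, len(name) - 1))  # transposition
    return name[:i] + name[i + 1] + name[i] + name[i + 2 :]


def _perturb_dob(dob: date, rng: np.random.Generator) -> date:
    """Alter one uniformly chosen birth-date component to another valid value."""
    comp = rng.integers(0, 3)
    if comp == 0:  # year
        year = dob.year + int(rng.choice([-2, -1, 1, 2]))
        day = min(dob.day, calendar.monthrange(year, dob.month)[1])
        return date(year, dob.month, day)
    if comp == 1:  # month
        choices = [m for m in range(1, 13) if m != dob.month]
        month = int(choices[rng.integers(0, 11)])
        day = min(dob.day, calendar.monthrange(dob.year, month)[1])
        return date(dob.year, month, day)
    ndays = calendar.monthrange(dob.year, dob.month)[1]
    choices = [d for d in range(1, ndays + 1) if d != dob.day]
    return date(dob.year, dob.month, int(choices[rng.integers(0, len(choices))]))


def corrupt_identifiers(person: TruePerson, model: ErrorModel, seed: int) -> dict:
    """One source's (possibly corrupted) view of a person's identifiers.

    Each corruption is applied independently with its configured
    probability; with all probabilities zero the returned record equals the
    truth, with the final residence interval as the reported residence.
    Returns a plain dict with keys first_name, last_name, sex, birth_date,
    death_date, state, zip (None = missing).
    """
    rng = np.random.default_rng(seed)
    u = rng.random(7)

    first = person.first_name
    last = person.last_name
    if u[0] < model.p_nickname:
        variants = model.nickname_table.get(first)
        if variants:
            first = variants[rng.integers(0, len(variants))]
    if u[1] < model.p_typo:
        first = _apply_typo(first, rng)
    if u[2] < model.p_typo:
        last = _apply_typo(last, rng)

    dob = person.birth_date
    if u[3] < model.p_dob_component_error:
        dob = _perturb_dob(dob, rng)
    if u[4] < model.p_dob_daymonth_swap and dob.day <= 12 and dob.day != dob.month:
        dob = date(dob.year, dob.day, dob.month)

    sex = person.sex
    if u[5] < model.p_sex_miscode:
        sex = "F" if sex == "M" else "M"

    state, zip_code, _ = person.residence_history[-1]
    if u[6] < model.p_zip_stale and len(person.residence_history) > 1:
        state, zip_code, _ = person.residence_history[
            rng.integers(0, len(person.residence_history) - 1)
        ]

    record = {
        "first_name": first,
        "last_name": last,
        "sex": sex,
        "birth_date": dob,
        "death_date": person.death_date,
        "state": state,
        "zip": zip_code,
    }
    if model.p_missing_field > 0:
        for key in ("first_name", "last_name", "sex", "birth_date", "state", "zip"):
            if rng.random() < model.p_missing_field:
                record[key] = None
    return record


@dataclass
class EventBundle:
    """Per-person event streams produced by :func:`generate_events`."""

    license_phases: list  # [(phase, start_date, end_date)]
    crash_involvements: list  # [{"injured": bool}]
    citations: list  # [(date, type)]
    suspensions: list  # [(start_date, restoration_date, type)]
    enrollment: list  # [(year, [12 monthly codes "FFS"/"MA"/""])]
    condition_onsets: dict  # condition -> date


def _alive_window(person: TruePerson, years: tuple[int, int]) -> tuple[int, int] | None:
    """Ordinal [start, end] day range the person is alive within the window."""
    w0 = (date(years[0], 1, 1) - _EPOCH).days
    w1 = (date(years[1], 12, 31) - _EPOCH).days
    b = (person.birth_date - _EPOCH).days
    d = (person.death_date - _EPOCH).days if person.death_date else w1
    lo, hi = max(w0, b), min(w1, d)
    return (lo, hi) if lo <= hi else None


def generate_events(
    person: TruePerson,
    model: EventModel,
    years: tuple[int, int],
    seed: int,
) -> EventBundle:
    """Simulate one person's license phases, traffic events, coverage, and
    chronic-condition onsets over the calendar window ``years``.

    Traffic events are homogeneous Poisson processes over the person's
    alive days within the window. Enrollment months exist only between the
    65th birthday month and the month of death; the plan (fee-for-service
    vs. capitated) is elected once per calendar year. License phases are
    administrative intervals and may extend past death.
    """
    if years[1] < years[0]:
        raise ValueError(f"empty date range: {years}")
    rng = np.random.default_rng(seed)
    alive = _alive_window(person, years)
    # the registry's licensing data reach back before the claims overlap
    era = _alive_window(person, (min(years[0], _REGISTRY_ERA_START), years[1]))

    # license phases (registry side)
    phases: list = []
    w0 = (date(years[0], 1, 1) - _EPOCH).days
    w1 = (date(years[1], 12, 31) - _EPOCH).days
    if person.in_sho and era is not None:
        if rng.random() < model.p_licensed_full_year:
            full_start = w0 - int(rng.integers(365, 20 * 365))
            full_end = w1 + 1 + int(rng.integers(1, 1000))
        elif rng.random() < 0.5:  # lapsed during the window
            full_end = int(rng.integers(w0 + 1, w1 + 1))
            full_start = full_end - int(rng.integers(5 * 365, 30 * 365))
        else:  # (re)licensed during the window
            full_start = int(rng.integers(w0 + 1, w1 + 1))
            full_end = w1 + 1 + int(rng.integers(1, 1000))
        # learner phases sit at ages ~17-18.5, decades before the claims era
        b = (person.birth_date - _EPOCH).days
        permit_start = b + int(17 * 365.25)
        phases = [
            ("permit", _from_ordinal_days(permit_start), _from_ordinal_days(permit_start + 183)),
            ("probationary", _from_ordinal_days(permit_start + 183), _from_ordinal_days(permit_start + 548)),
            ("full", _from_ordinal_days(full_start), _from_ordinal_days(full_end)),
        ]

    crashes: list = []
    citations: list = []
    suspensions: list = []
    if person.in_sho and alive is not None:
        exposure_years = (alive[1] - alive[0] + 1) / 365.25
        for _ in range(rng.poisson(model.crash_rate * exposure_years)):
            crashes.append({"injured": bool(rng.random() < model.p_crash_injury)})
        for _ in range(rng.poisson(model.citation_rate * exposure_years)):
            d = int(rng.integers(alive[0], alive[1] + 1))
            citations.append(
                (_from_ordinal_days(d), pools.CITATION_TYPES[rng.integers(0, len(pools.CITATION_TYPES))])
            )
        for _ in range(rng.poisson(model.suspension_rate * exposure_years)):
            s = int(rng.integers(alive[0], alive[1] + 1))
            suspensions.append(
                (
                    _from_ordinal_days(s),
                    _from_ordinal_days(s + int(rng.integers(30, 366))),
                    pools.SUSPENSION_TYPES[rng.integers(0, len(pools.SUSPENSION_TYPES))],
                )
            )

    enrollment: list = []
    if person.in_medicare:
        d65 = person.age65_date
        death = person.death_date
        last_year = min(years[1], death.year if death else years[1])
        plan_is_ffs = rng.random(max(0, last_year - years[0] + 1)) < model.p_ffs_month
        for yi, year in enumerate(range(max(years[0], d65.year), last_year + 1)):
            if death and (death.year < year or (death.year == year and death < date(year, 1, 1))):
                break
            code = "FFS" if plan_is_ffs[year - years[0]] else "MA"
            months = []
            for mo in range(1, 13):
                covered = True
                if year == d65.year and mo < d65.month:
                    covered = False
                if death and (year > death.year or (year == death.year and mo > death.month)):
                    covered = False
                months.append(code if covered else "")
            if any(months):
                enrollment.append((year, months))

    onsets: dict = {}
    if person.in_medicare:
        end_bound = min(person.death_date or _HORIZON, date(years[1], 12, 31))
        lo = (_shift_years(person.birth_date, 45) - _EPOCH).days
        hi = (end_bound - _EPOCH).days
        for cond, prev in model.chronic_condition_prevalences.items():
            if rng.random() < prev and lo < hi:
                onsets[cond] = _from_ordinal_days(int(rng.integers(lo, hi + 1)))

    return EventBundle(phases, crashes, citations, suspensions, enrollment, onsets)


SOURCE_FILES = {
    "licensing": "sho_licensing.csv",
    "citations": "sho_citations.csv",
    "suspensions": "sho_suspensions.csv",
    "crash_crashlevel": "sho_crash_crashlevel.csv",
    "crash_driverlevel": "sho_crash_driverlevel.csv",
    "mbsf": "medicare_mbsf.csv",
    "truth": "truth_crosswalk.csv",
}


def _iso(d: date | None) -> str:
    return d.isoformat() if d else ""


def export_sources(
    population: list[TruePerson],
    out_dir: str | Path,
    error_model: ErrorModel = DEFAULT_ERROR_MODEL,
    event_model: EventModel = DEFAULT_EVENT_MODEL,
    years: tuple[int, int] = (2007, 2019),
    seed: int = 0,
) -> dict[str, Path]:
    """Write both synthetic sources plus the ground-truth crosswalk.

    Produces the registry files (licensing, citations, suspensions, crash-
    and driver-level crash data), the beneficiary summary file, and
    ``truth_crosswalk.csv`` mapping each registry row to its true
    beneficiary record. Comma-separated, header row, ISO-8601 dates, empty
    string for missing. Returns a name -> path mapping.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    n = len(population)
    seeds_sho = master.integers(0, 2**31 - 1, size=n)
    seeds_bene = master.integers(0, 2**31 - 1, size=n)
    seeds_events = master.integers(0, 2**31 - 1, size=n)
    rng_pair = np.random.default_rng(master.integers(0, 2**31 - 1))

    lic_rows, cit_rows, susp_rows, drv_rows, mbsf_rows, truth_rows = [], [], [], [], [], []
    involvements = []  # (person_index, sho_row_id, injured)
    sho_row_ids: dict[int, str] = {}
    bene_ids: dict[int, str] = {}

    cond_names = list(event_model.chronic_condition_prevalences)

    for i, person in enumerate(population):
        events = generate_events(person, event_model, years, int(seeds_events[i]))
        if person.in_sho:
            row_id = f"R{i:07d}"
            sho_row_ids[i] = row_id
            view = corrupt_identifiers(person, error_model, int(seeds_sho[i]))
            base = {
                "sho_row_id": row_id,
                "first_name": view["first_name"] or "",
                "last_name": view["last_name"] or "",
                "sex": view["sex"] or "",
                "birth_date": _iso(view["birth_date"]),
                "death_date": _iso(view["death_date"]),
                "state": view["state"] or "",
                "zip": view["zip"] or "",
            }
            for phase, start, end in events.license_phases:
                lic_rows.append({**base, "phase": phase, "phase_start": _iso(start), "phase_end": _iso(end)})
            if not events.license_phases:
                # registry membership may come from a crash alone
                pass
            for d, ctype in events.citations:
                cit_rows.append({"sho_row_id": row_id, "citation_date": _iso(d), "citation_type": ctype})
            for s, r, stype in events.suspensions:
                susp_rows.append(
                    {"sho_row_id": row_id, "suspension_start": _iso(s), "restoration_date": _iso(r), "suspension_type": stype}
                )
            for inv in events.crash_involvements:
                involvements.append((i, base, inv["injured"]))
        if person.in_medicare:
            bene_id = f"BENE{i:011d}"
            bene_ids[i] = bene_id
            view = corrupt_identifiers(person, error_model, int(seeds_bene[i]))
            onset_cols = {
                f"cond_{c}": _iso(events.condition_onsets.get(c)) for c in cond_names
            }
            for year, months in events.enrollment:
                row = {
                    "bene_id": bene_id,
                    "year": year,
                    "first_name": view["first_name"] or "",
                    "last_name": view["last_name"] or "",
                    "sex": view["sex"] or "",
                    "birth_date": _iso(view["birth_date"]),
                    "death_date": _iso(view["death_date"]),
                    "state": view["state"] or "",
                    "zip": view["zip"] or "",
                    "race_ethnicity": person.race_ethnicity,
                }
                for mo in range(1, 13):
                    row[f"cov_{mo:02d}"] = months[mo - 1]
                row.update(onset_cols)
                mbsf_rows.append(row)
        if person.in_sho and person.in_medicare and i in bene_ids:
            truth_rows.append(
                {"person_uid": person.person_uid, "sho_row_id": f"R{i:07d}", "bene_id": bene_ids[i]}
            )

    # assemble crash records; a fraction of involvements pair into two-driver crashes
    crash_rows = []
    order = rng_pair.permutation(len(involvements))
    paired: dict[int, int] = {}
    pending = None
    for k in order:
        if pending is None:
            if rng_pair.random() < event_model.p_two_driver_crash:
                pending = k
            continue
        a, b = pending, int(k)
        wa = _alive_window(population[involvements[a][0]], years)
        wb = _alive_window(population[involvements[b][0]], years)
        if wa and wb and max(wa[0], wb[0]) <= min(wa[1], wb[1]):
            paired[a] = b
            paired[b] = a
        pending = None

    crash_counter = 0
    assigned: dict[int, str] = {}
    for k, (pi, base, injured) in enumerate(involvements):
        if k in assigned:
            continue
        crash_counter += 1
        crash_id = f"C{crash_counter:07d}"
        members = [k] + ([paired[k]] if k in paired and paired[k] > k else [])
        if k in paired and paired[k] < k:
            members = [k]  # partner already emitted its crash; defensive, unreachable
        windows = [_alive_window(population[involvements[m][0]], years) for m in members]
        lo = max(w[0] for w in windows)
        hi = min(w[1] for w in windows)
        crash_day = int(rng_pair.integers(lo, hi + 1))
        n_injured = sum(involvements[m][2] for m in members)
        if n_injured == 0:
            damage = 500 + int(rng_pair.lognormal(7.0, 1.0))
        else:
            damage = int(rng_pair.lognormal(7.5, 1.2))
        crash_rows.append(
            {
                "crash_id": crash_id,
                "crash_date": _iso(_from_ordinal_days(crash_day)),
                "n_vehicles": len(members),
                "n_injured": n_injured,
                "total_damage": damage,
            }
        )
        for m in members:
            assigned[m] = crash_id
            _, mbase, minj = involvements[m]
            drv_rows.append({**mbase, "crash_id": crash_id, "driver_injured": int(minj)})

    paths = {}
    frames = {
        "licensing": pd.DataFrame(
            lic_rows,
            columns=["sho_row_id", "first_name", "last_name", "sex", "birth_date",
                     "death_date", "state", "zip", "phase", "phase_start", "phase_end"],
        ),
        "citations": pd.DataFrame(cit_rows, columns=["sho_row_id", "citation_date", "citation_type"]),
        "suspensions": pd.DataFrame(
            susp_rows, columns=["sho_row_id", "suspension_start", "restoration_date", "suspension_type"]
        ),
        "crash_crashlevel": pd.DataFrame(
            crash_rows, columns=["crash_id", "crash_date", "n_vehicles", "n_injured", "total_damage"]
        ),
        "crash_driverlevel": pd.DataFrame(
            drv_rows,
            columns=["sho_row_id", "first_name", "last_name", "sex", "birth_date",
                     "death_date", "state", "zip", "crash_id", "driver_injured"],
        ),
        "mbsf": pd.DataFrame(
            mbsf_rows,
            columns=["bene_id", "year", "first_name", "last_name", "sex", "birth_date",
                     "death_date", "state", "zip", "race_ethnicity"]
            + [f"cov_{mo:02d}" for mo in range(1, 13)]
            + [f"cond_{c}" for c in cond_names],
        ),
        "truth": pd.DataFrame(truth_rows, columns=["person_uid", "sho_row_id", "bene_id"]),
    }
    for key, frame in frames.items():
        path = out_dir / SOURCE_FILES[key]
        frame.to_csv(path, index=False, lineterminator="\n")
        paths[key] = path
    return paths
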