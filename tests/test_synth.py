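"""Synthetic-data generator: determinism, error operators, event processes."""

import math
from datetime import date

import numpy as np
import pytest

from sholink.synth import (
    DEFAULT_ERROR_MODEL,
    DEFAULT_EVENT_MODEL,
    ZERO_ERROR_MODEL,
    ErrorModel,
    EventModel,
    corrupt_identifiers,
    export_sources,
    generate_events,
    generate_population,
)


def _person(**kw):
    from sholink.synth import TruePerson

    defaults = dict(
        person_uid="P0",
        first_name="John",
        last_name="Smith",
        sex="M",
        birth_date=date(1950, 3, 4),
        death_date=None,
        residence_history=[("NJ", "08901", date(1968, 5, 1))],
        race_ethnicity="Non-Hispanic White",
        in_sho=True,
        in_medicare=True,
    )
    defaults.update(kw)
    return TruePerson(**defaults)


class TestGeneratePopulation:
    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            generate_population(0, seed=1)

    def test_full_overlap_flags_every_person_for_both_sources(self):
        for p in generate_population(1000, seed=7, overlap=1.0):
            assert p.in_sho and p.in_medicare

    def test_seeded_runs_identical(self):
        a = generate_population(1000, seed=7)
        b = generate_population(1000, seed=7)
        assert a == b

    def test_overlap_fraction_within_three_binomial_ses(self):
        n, overlap = 10000, 0.9
        pop = generate_population(n, seed=3, overlap=overlap)
        frac = sum(p.in_sho and p.in_medicare for p in pop) / n
        se = math.sqrt(overlap * (1 - overlap) / n)
        assert abs(frac - overlap) <= 3 * se

    def test_person_invariants(self):
        for p in generate_population(2000, seed=11):
            assert 1900 <= p.birth_date.year <= 1954
            if p.death_date is not None:
                assert p.death_date >= p.birth_date
            starts = [s for _, _, s in p.residence_history]
            assert starts == sorted(starts)
            assert p.in_sho or p.in_medicare


class TestCorruptIdentifiers:
    def test_zero_error_model_is_identity(self):
        p = _person()
        rec = corrupt_identifiers(p, ZERO_ERROR_MODEL, seed=5)
        assert rec["first_name"] == "John"
        assert rec["last_name"] == "Smith"
        assert rec["sex"] == "M"
        assert rec["birth_date"] == p.birth_date
        assert rec["death_date"] is None
        assert (rec["state"], rec["zip"]) == ("NJ", "08901")

    def test_forced_nickname_substitutes_variant(self):
        model = ErrorModel(
            p_nickname=1.0, p_typo=0, p_dob_component_error=0, p_dob_daymonth_swap=0,
            p_sex_miscode=0, p_zip_stale=0, p_missing_field=0,
            nickname_table={"John": ["Jon"]},
        )
        rec = corrupt_identifiers(_person(), model, seed=5)
        assert rec["first_name"] == "Jon"

    def test_forced_daymonth_swap(self):
        model = ErrorModel(
            p_nickname=0, p_typo=0, p_dob_component_error=0, p_dob_daymonth_swap=1.0,
            p_sex_miscode=0, p_zip_stale=0, p_missing_field=0,
        )
        rec = corrupt_identifiers(_person(birth_date=date(1950, 3, 4)), model, seed=5)
        assert rec["birth_date"] == date(1950, 4, 3)

    def test_dob_perturbation_yields_valid_different_date(self):
        model = ErrorModel(
            p_nickname=0, p_typo=0, p_dob_component_error=1.0, p_dob_daymonth_swap=0,
            p_sex_miscode=0, p_zip_stale=0, p_missing_field=0,
        )
        p = _person(birth_date=date(1948, 1, 31))
        for seed in range(40):
            rec = corrupt_identifiers(p, model, seed=seed)
            assert isinstance(rec["birth_date"], date)
            assert rec["birth_date"] != p.birth_date

    def test_stale_zip_uses_earlier_residence(self):
        p = _person(
            residence_history=[
                ("NJ", "07001", date(1968, 5, 1)),
                ("NJ", "08901", date(1995, 6, 1)),
            ]
        )
        model = ErrorModel(
            p_nickname=0, p_typo=0, p_dob_component_error=0, p_dob_daymonth_swap=0,
            p_sex_miscode=0, p_zip_stale=1.0, p_missing_field=0,
        )
        rec = corrupt_identifiers(p, model, seed=5)
        assert rec["zip"] == "07001"

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(p_typo=1.5)


class TestGenerateEvents:
    def test_zero_crash_rate_yields_no_crashes(self):
        model = EventModel(crash_rate=0.0)
        ev = generate_events(_person(), model, years=(2019, 2019), seed=3)
        assert ev.crash_involvements == []

    def test_empty_date_range_rejected(self):
        with pytest.raises(ValueError):
            generate_events(_person(), DEFAULT_EVENT_MODEL, years=(2019, 2018), seed=3)

    def test_no_enrollment_months_after_death(self):
        p = _person(death_date=date(2019, 6, 15))
        ev = generate_events(p, DEFAULT_EVENT_MODEL, years=(2019, 2019), seed=3)
        (year, months), = ev.enrollment
        assert year == 2019
        assert all(m == "" for m in months[6:])  # July onward uncovered
        assert any(m != "" for m in months[:6])

    def test_enrollment_starts_at_65th_birthday_month(self):
        p = _person(birth_date=date(1954, 8, 20))
        ev = generate_events(p, DEFAULT_EVENT_MODEL, years=(2019, 2019), seed=3)
        (year, months), = ev.enrollment
        assert year == 2019
        assert months[:7] == [""] * 7 and months[7] != ""

    def test_crash_dates_only_while_alive(self, tmp_path):
        pop = generate_population(800, seed=21)
        paths = export_sources(pop, tmp_path, years=(2015, 2019), seed=21)
        import pandas as pd

        crash = pd.read_csv(paths["crash_crashlevel"], dtype=str)
        drivers = pd.read_csv(paths["crash_driverlevel"], dtype=str)
        deaths = {f"R{i:07d}": p.death_date for i, p in enumerate(pop)}
        merged = drivers.merge(crash, on="crash_id")
        for rid, d in zip(merged["sho_row_id"], merged["crash_date"]):
            dd = deaths[rid]
            assert dd is None or date.fromisoformat(d) <= dd

    def test_crash_involvement_rate_near_poisson_expectation(self):
        """10,000 person-years at the default crash rate: the crash-involved
        fraction sits within 3 binomial SEs of 1 - exp(-rate)."""
        model = EventModel(crash_rate=0.0247)
        pop = generate_population(10000, seed=13, overlap=1.0)
        alive = [p for p in pop if p.death_date is None or p.death_date > date(2019, 12, 31)]
        hits = 0
        for i, p in enumerate(alive):
            ev = generate_events(p, model, years=(2019, 2019), seed=1000 + i)
            hits += bool(ev.crash_involvements)
        p0 = 1 - math.exp(-0.0247)
        se = math.sqrt(p0 * (1 - p0) / len(alive))
        assert abs(hits / len(alive) - p0) <= 3 * se


class TestExportSources:
    def test_seeded_exports_byte_identical(self, tmp_path):
        pop = generate_population(300, seed=9)
        p1 = export_sources(pop, tmp_path / "a", years=(2018, 2019), seed=9)
        p2 = export_sources(pop, tmp_path / "b", years=(2018, 2019), seed=9)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_truth_crosswalk_covers_dual_source_persons(self, tmp_path):
        import pandas as pd

        pop = generate_population(300, seed=9)
        paths = export_sources(pop, tmp_path, years=(2018, 2019), seed=9)
        truth = pd.read_csv(paths["truth"], dtype=str)
        n_both = sum(p.in_sho and p.in_medicare for p in pop)
        assert len(truth) == n_both
        assert truth["sho_row_id"].is_unique and truth["bene_id"].is_unique

    def test_two_driver_crashes_share_crash_id(self, tmp_path):
        import pandas as pd

        pop = generate_population(3000, seed=17)
        paths = export_sources(
            pop, tmp_path, event_model=EventModel(crash_rate=0.3, p_two_driver_crash=0.5),
            years=(2015, 2019), seed=17,
        )
        crash = pd.read_csv(paths["crash_crashlevel"])
        drivers = pd.read_csv(paths["crash_driverlevel"])
        counts = drivers.groupby("crash_id").size()
        two = crash.loc[crash["n_vehicles"] == 2, "crash_id"]
        assert len(two) > 0
        assert (counts.loc[two] == 2).all()
        assert (counts.loc[crash.loc[crash["n_vehicles"] == 1, "crash_id"]] == 1).all()

    def test_reportable_crash_rule(self, tmp_path):
        import pandas as pd

        pop = generate_population(3000, seed=19)
        paths = export_sources(
            pop, tmp_path, event_model=EventModel(crash_rate=0.3), years=(2015, 2019), seed=19
        )
        crash = pd.read_csv(paths["crash_crashlevel"])
        assert ((crash["total_damage"] >= 500) | (crash["n_injured"] > 0)).all()
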