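"""Category comparators, blocking, and bulk scoring."""

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sholink import names as pools
from sholink.matching import (
    block_candidates,
    compare_age,
    compare_name,
    compare_residence,
    compare_sex,
    prepare_identifiers,
    score_candidates,
    score_pair,
)
from sholink.quality import Quality
from sholink.textcomp import canonicalize_name, damerau_osa, jaro_winkler

H, M, L, N = Quality.HIGH, Quality.MEDIUM, Quality.LOW, Quality.NONE


class TestCompareName:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("John", "Smith"), ("John", "Smith"), H),
            (("John", "Smith"), ("Jon", "Smith"), M),  # nickname-type variant
            (("John", "Smith"), ("Frank", "Smith"), L),  # unrelated first name
            (("JOHN", "SMITH"), ("john", "smith"), H),  # case-insensitive
            (("Mary-Jane", "O'Brien"), ("Maryjane", "OBrien"), H),
            (("John", "Smith"), ("John", "Smiht"), M),  # surname typo, exact first
            (("Jon", "Smith"), ("John", "Smiht"), N),  # surname typo + first variant
            (("John", "Smith"), ("John", "Miller"), N),
            (("", "Smith"), ("John", "Smith"), N),  # missing field
        ],
    )
    def test_rule_ladder(self, a, b, expected):
        assert compare_name(a[0], a[1], b[0], b[1]) is expected

    def test_variant_variant_nickname_hit(self):
        # both record views nicknamed from the same canonical name
        assert compare_name("Betty", "Jones", "Liz", "Jones") is M
        assert compare_name("Jon", "Jones", "Johnny", "Jones") is M


class TestCompareSexAgeResidence:
    def test_sex(self):
        assert compare_sex("F", "F") is H
        assert compare_sex("F", "M") is N
        assert compare_sex("F", "") is N
        assert compare_sex(None, None) is N

    @pytest.mark.parametrize(
        "dob_a, dob_b, expected",
        [
            (date(1950, 3, 4), date(1950, 3, 4), H),
            (date(1950, 3, 4), date(1950, 4, 3), M),  # day/month transposed
            (date(1950, 3, 4), date(1950, 3, 14), M),  # one component off
            (date(1950, 3, 4), date(1950, 7, 4), M),
            (date(1950, 3, 4), date(1951, 3, 4), L),  # year off by one
            (date(1950, 3, 4), date(1950, 7, 14), L),  # same year, two off
            (date(1950, 3, 4), date(1958, 3, 4), N),
            (None, date(1950, 3, 4), N),
        ],
    )
    def test_age_rule_table(self, dob_a, dob_b, expected):
        assert compare_age(dob_a, None, dob_b, None) is expected

    def test_death_date_conflict_caps_at_low(self):
        dob = date(1950, 3, 4)
        assert compare_age(dob, date(2018, 1, 1), dob, date(2018, 1, 2)) is L
        assert compare_age(dob, date(2018, 1, 1), dob, date(2018, 1, 1)) is H
        assert compare_age(dob, date(2018, 1, 1), dob, None) is H  # missing compatible

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("NJ", "08901"), ("NJ", "08901"), H),
            (("NJ", "08901"), ("NJ", "08902"), M),  # shared 3-digit prefix
            (("NJ", "08901"), ("NJ", "07302"), L),  # state only
            (("NJ", "08901"), ("PA", "19104"), N),
            (("", "08901"), ("NJ", "08901"), N),
        ],
    )
    def test_residence_rule_table(self, a, b, expected):
        assert compare_residence(a[0], a[1], b[0], b[1]) is expected


_rec = st.fixed_dictionaries(
    {
        "first_name": st.sampled_from(["John", "Jon", "Frank", "Mary", ""]),
        "last_name": st.sampled_from(["Smith", "Smiht", "Miller", ""]),
        "sex": st.sampled_from(["F", "M", ""]),
        "birth_date": st.one_of(
            st.none(), st.dates(min_value=date(1949, 1, 1), max_value=date(1951, 12, 31))
        ),
        "death_date": st.one_of(
            st.none(), st.dates(min_value=date(2017, 1, 1), max_value=date(2018, 12, 31))
        ),
        "state": st.sampled_from(["NJ", "PA", ""]),
        "zip": st.sampled_from(["08901", "08902", "07302", ""]),
    }
)


@settings(derandomize=True, max_examples=300)
@given(_rec, _rec)
def test_all_comparators_symmetric(rec_a, rec_b):
    assert score_pair(rec_a, rec_b) == score_pair(rec_b, rec_a)


@pytest.mark.parametrize(
    "field, worse",
    [
        ("first_name", "Frank"),  # John -> unrelated name
        ("sex", "M"),
        ("birth_date", date(1950, 4, 4)),
        ("zip", "07302"),
        ("state", "PA"),
    ],
)
def test_monotone_degradation_single_field(field, worse):
    """Injecting one additional error never raises that category's quality."""
    base = {
        "first_name": "John", "last_name": "Smith", "sex": "F",
        "birth_date": date(1950, 3, 4), "death_date": None,
        "state": "NJ", "zip": "08901",
    }
    clean = score_pair(base, base)
    dirty = score_pair(base, {**base, field: worse})
    for cat in ("name", "sex", "age", "residence"):
        assert getattr(dirty, cat) <= getattr(clean, cat)


def test_score_pair_composes_categories():
    rec = {
        "first_name": "John", "last_name": "Smith", "sex": "M",
        "birth_date": date(1950, 3, 4), "death_date": None,
        "state": "NJ", "zip": "08901",
    }
    assert score_pair(rec, rec).astuple() == (H, H, H, H)
    variant = {**rec, "first_name": "Jon"}
    assert score_pair(rec, variant).astuple() == (M, H, H, H)


# ---------------------------------------------------------------------------
# bulk path
# ---------------------------------------------------------------------------


def _source_frames(run):
    finder = run.read("finder_file.csv")
    mbsf = run.read("medicare_mbsf.csv")
    bene = mbsf.sort_values("year").drop_duplicates("bene_id", keep="last")
    return finder, bene


def test_blocking_contains_exact_and_recovers_truth(zero_error_run):
    finder, bene = _source_frames(zero_error_run)
    truth = zero_error_run.read("truth_crosswalk.csv")
    pairs = block_candidates(prepare_identifiers(finder), prepare_identifiers(bene))
    got = set(zip(pairs["sho_id"], pairs["bene_id"]))
    id_map = finder.set_index("sho_row_id")["sho_id"]
    present_bene = set(bene["bene_id"])
    expected = {
        (id_map[r], b)
        for r, b in zip(truth["sho_row_id"], truth["bene_id"])
        if r in id_map.index and b in present_bene
    }
    # zero-error truth pairs agree on all six identifiers -> all generated
    assert expected <= got
    assert pairs.duplicated(["sho_id", "bene_id"]).sum() == 0


def test_bulk_scoring_matches_scalar_scoring(default_error_run):
    """Vectorized scores equal record-by-record comparator composition."""
    finder, bene = _source_frames(default_error_run)
    finder, bene = finder.head(150), bene.head(150)
    a, b = prepare_identifiers(finder), prepare_identifiers(bene)
    scored = score_candidates(a, b)
    assert len(scored) > 0

    def rec(row):
        def dt(v):
            return date.fromisoformat(v) if v else None

        return {
            "first_name": row["first_name"], "last_name": row["last_name"],
            "sex": row["sex"], "birth_date": dt(row["birth_date"]),
            "death_date": dt(row["death_date"]), "state": row["state"], "zip": row["zip"],
        }

    fa = finder.set_index("sho_id")
    fb = bene.set_index("bene_id")
    for _, row in scored.iterrows():
        q = score_pair(rec(fa.loc[row["sho_id"]]), rec(fb.loc[row["bene_id"]]))
        assert (row["q_name"], row["q_sex"], row["q_age"], row["q_residence"]) == q.astuple(), (
            row["sho_id"], row["bene_id"])


def test_blocked_pairs_agreeing_on_surname_and_birth_year_are_complete(default_error_run):
    """Brute-force check: every cross-pair with equal canonical surname and
    birth year (a fortiori every all-six-field agreement) is generated."""
    finder, bene = _source_frames(default_error_run)
    finder, bene = finder.head(200), bene.head(200)
    a, b = prepare_identifiers(finder), prepare_identifiers(bene)
    pairs = set(map(tuple, block_candidates(a, b)[["sho_id", "bene_id"]].to_numpy()))
    merged = a.merge(b, on=["_last", "_by"], suffixes=("_a", "_b"))
    for s, e in zip(merged["sho_id"], merged["bene_id"]):
        assert (s, e) in pairs


# ---------------------------------------------------------------------------
# fixture pool invariants
# ---------------------------------------------------------------------------


def test_canonical_name_pools_are_pairwise_dissimilar():
    """No two distinct canonical persons can reach a Medium name quality on
    uncorrupted data: given names are >= 2 keystroke edits apart, below the
    Jaro-Winkler threshold, and not nickname-related; surnames >= 2 edits."""
    firsts = sorted({canonicalize_name(n) for n in pools.MALE_FIRST + pools.FEMALE_FIRST})
    nick = pools.nickname_pairs()
    assert len(firsts) == len(pools.MALE_FIRST) + len(pools.FEMALE_FIRST)
    for i, a in enumerate(firsts):
        for b in firsts[i + 1 :]:
            assert damerau_osa(a, b) >= 2, (a, b)
            assert jaro_winkler(a, b) < 0.88, (a, b)
            assert frozenset((a, b)) not in nick, (a, b)
    lasts = sorted({canonicalize_name(n) for n in pools.SURNAMES})
    assert len(lasts) == len(pools.SURNAMES)
    for i, a in enumerate(lasts):
        for b in lasts[i + 1 :]:
            assert damerau_osa(a, b) >= 2, (a, b)
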