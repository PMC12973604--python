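"""Confidence assignment, one-to-many resolution, and acceptance strategies."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from sholink.classify import (
    DEFAULT_PATTERN_TABLE,
    ConfidencePatternTable,
    add_confidence,
    apply_strategy,
    assign_confidence,
    build_crosswalk,
    percent,
    resolve_one_to_many,
    strategy_mask,
    strategy_report,
)
from sholink.quality import CategoryQualities, Confidence, Quality

H, M, L, N = Quality.HIGH, Quality.MEDIUM, Quality.LOW, Quality.NONE
ALL_PATTERNS = [CategoryQualities(*combo) for combo in product(Quality, repeat=4)]


class TestConfidence:
    def test_anchor_patterns(self):
        assert assign_confidence(CategoryQualities(H, H, H, H)) is Confidence.STRONG
        assert assign_confidence(CategoryQualities(H, M, M, M)) is Confidence.FAIR
        assert assign_confidence(CategoryQualities(N, N, N, N)) is Confidence.WEAK

    def test_frame_assignment_matches_scalar(self):
        df = pd.DataFrame(
            [
                {"q_name": int(q.name), "q_sex": int(q.sex), "q_age": int(q.age),
                 "q_residence": int(q.residence)}
                for q in ALL_PATTERNS
            ]
        )
        vec = DEFAULT_PATTERN_TABLE.assign_frame(df)
        for i, q in enumerate(ALL_PATTERNS):
            assert vec[i] == int(assign_confidence(q))

    def test_table_round_trips_through_config_form(self):
        rebuilt = ConfidencePatternTable.from_list(DEFAULT_PATTERN_TABLE.to_list())
        for q in ALL_PATTERNS:
            assert rebuilt.assign(q) is DEFAULT_PATTERN_TABLE.assign(q)

    def test_first_matching_pattern_wins(self):
        table = ConfidencePatternTable.from_list(
            [
                {"pattern": {"name": "High"}, "confidence": "Strong"},
                {"pattern": {"name": "Medium"}, "confidence": "Fair"},
            ]
        )
        assert table.assign(CategoryQualities(H, N, N, N)) is Confidence.STRONG
        assert table.assign(CategoryQualities(M, N, N, N)) is Confidence.FAIR
        assert table.assign(CategoryQualities(L, N, N, N)) is Confidence.WEAK


def _frame(rows):
    return pd.DataFrame(
        [
            {
                "sho_id": s, "bene_id": b,
                "q_name": int(q[0]), "q_sex": int(q[1]),
                "q_age": int(q[2]), "q_residence": int(q[3]),
            }
            for s, b, q in rows
        ]
    )


class TestResolution:
    def test_best_candidate_kept_for_contested_sho(self):
        df = add_confidence(_frame([
            ("S1", "B1", (H, H, H, H)),
            ("S1", "B2", (H, H, M, H)),
        ]))
        kept, dropped = resolve_one_to_many(df)
        assert list(kept["bene_id"]) == ["B1"]
        assert list(dropped["bene_id"]) == ["B2"]
        assert kept["cardinality"].iloc[0] == "one_to_many_resolved"

    def test_already_one_to_one_is_identity(self):
        df = add_confidence(_frame([
            ("S1", "B1", (H, H, H, H)),
            ("S2", "B2", (M, H, H, L)),
        ]))
        kept, dropped = resolve_one_to_many(df)
        assert len(dropped) == 0
        assert set(kept["cardinality"]) == {"one_to_one"}
        assert set(zip(kept["sho_id"], kept["bene_id"])) == {("S1", "B1"), ("S2", "B2")}

    def test_tie_broken_toward_smaller_sho_id(self):
        df = add_confidence(_frame([
            ("S2", "B1", (H, H, H, H)),
            ("S1", "B1", (H, H, H, H)),
        ]))
        kept, dropped = resolve_one_to_many(df)
        assert list(kept["sho_id"]) == ["S1"]
        assert list(dropped["sho_id"]) == ["S2"]

    def test_output_ids_unique_on_random_input(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"S{rng.integers(0, 40)}", f"B{rng.integers(0, 40)}",
             tuple(Quality(v) for v in rng.integers(0, 4, 4)))
            for _ in range(300)
        ]
        df = add_confidence(_frame(rows).drop_duplicates(["sho_id", "bene_id"]))
        kept, dropped = resolve_one_to_many(df)
        assert kept["sho_id"].is_unique and kept["bene_id"].is_unique
        assert len(kept) + len(dropped) == len(df)


class TestStrategies:
    def test_all_high_accepted_everywhere(self):
        df = add_confidence(_frame([("S1", "B1", (H, H, H, H))]))
        for sid in range(1, 6):
            assert strategy_mask(df, sid).all()

    def test_two_high_pattern_splits_strategies(self):
        # name=M, sex=H, age=H, residence=M: only 2 Highs
        df = add_confidence(_frame([("S1", "B1", (M, H, H, M))]))
        assert not strategy_mask(df, 2)[0]
        for sid in (3, 4, 5):
            assert strategy_mask(df, sid)[0]

    def test_medium_age_pattern_splits_strategies(self):
        # name=H, sex=H, age=M, residence=H
        df = add_confidence(_frame([("S1", "B1", (H, H, M, H))]))
        assert not strategy_mask(df, 3)[0]
        for sid in (2, 4, 5):
            assert strategy_mask(df, sid)[0]

    def test_strategy5_acceptances_are_strong_or_fair_exhaustively(self):
        """Over all 4^4 quality combinations, the default pattern table gives
        every Strategy-5 acceptance a Strong or Fair confidence."""
        df = add_confidence(
            _frame([(f"S{i}", f"B{i}", q.astuple()) for i, q in enumerate(ALL_PATTERNS)])
        )
        accepted = df.loc[strategy_mask(df, 5)]
        assert (accepted["confidence"] >= int(Confidence.FAIR)).all()

    def test_subset_laws_exhaustive(self):
        df = add_confidence(
            _frame([(f"S{i}", f"B{i}", q.astuple()) for i, q in enumerate(ALL_PATTERNS)])
        )
        m3, m4, m5 = (strategy_mask(df, s) for s in (3, 4, 5))
        assert not (m3 & ~m4).any()
        assert not (m3 & ~m5).any()

    def test_unknown_strategy_rejected(self):
        df = add_confidence(_frame([("S1", "B1", (H, H, H, H))]))
        with pytest.raises(ValueError):
            strategy_mask(df, 6)


class TestReporting:
    @pytest.mark.parametrize(
        "count, denom, expected",
        [
            (2712325, 2906281, 93.33),
            (2661782, 2906281, 91.59),
            (2661782, 2722773, 97.76),
            (0, 2906281, 0.00),
            (1, 0, 0.00),
            (1, 8, 12.50),
            (1, 16, 6.25),
        ],
    )
    def test_percent_rounding_rule(self, count, denom, expected):
        assert percent(count, denom) == expected

    def test_strategy_report_counts_and_percents(self):
        df = add_confidence(_frame([
            ("S1", "B1", (H, H, H, H)),
            ("S2", "B2", (M, H, H, M)),
            ("S3", "B3", (N, N, N, N)),
        ]))
        rep = strategy_report(df, n_final_cohort=4).set_index("strategy")
        assert rep.loc[5, "accepted"] == 2
        assert rep.loc[5, "pct_of_final"] == 50.00
        assert rep.loc[2, "accepted"] == 1
        assert rep.loc[2, "pct_of_final"] == 25.00

    def test_crosswalk_bids_unique_and_deterministic(self):
        df = add_confidence(_frame([
            ("S2", "B2", (H, H, H, H)),
            ("S1", "B1", (H, H, H, H)),
        ]))
        xw = build_crosswalk(df)
        assert list(xw["sho_id"]) == ["S1", "S2"]
        assert xw["bid"].is_unique
        assert build_crosswalk(df).equals(xw)
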