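"""Apriori miner: supports, frequent itemsets, rules, brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symmine import (
    MiningConfig,
    MiningError,
    Rule,
    TransactionSet,
    TwoByTwo,
    brute_force_rules,
    frequent_itemsets,
    generate_rules,
    itemset_support,
    mine_rules,
    rule_metrics_from_counts,
)


def tset(raw):
    trans = tuple(frozenset(t) for t in raw)
    universe = frozenset().union(*trans) if trans else frozenset()
    return TransactionSet(trans, universe)


transaction_sets = st.lists(
    st.sets(st.sampled_from("ABCDEFGH"), max_size=8), min_size=1, max_size=40
).map(tset)


class TestItemsetSupport:
    def test_toy_pair_counted_by_hand(self, toy_transactions):
        # {A,B} appears in T1, T2, T6 of the six transactions
        assert itemset_support({"A", "B"}, toy_transactions) == 0.5

    def test_empty_itemset_vacuously_everywhere(self, toy_transactions):
        assert itemset_support(frozenset(), toy_transactions) == 1.0

    def test_fixture_polyuria_diabetes(self, fixture_transactions):
        s = itemset_support({"Polyuria=1", "Diabetes=1"}, fixture_transactions)
        assert s == 243 / 520

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(transaction_sets, st.sets(st.sampled_from("ABCDEFGH"), max_size=4),
           st.sampled_from("ABCDEFGH"))
    def test_anti_monotone_in_the_itemset(self, t, base, extra):
        # adding an item can only shrink the set of covering transactions
        assert itemset_support(base | {extra}, t) <= itemset_support(base, t) + 1e-15


class TestFrequentItemsets:
    def test_toy_enumeration_all_seven_sets(self, toy_transactions):
        got = frequent_itemsets(toy_transactions, min_support=0.5, max_size=3)
        flat = {tuple(sorted(s)): v for lvl in got.values() for s, v in lvl.items()}
        assert flat == {
            ("A",): 4 / 6,
            ("B",): 4 / 6,
            ("D",): 5 / 6,
            ("A", "B"): 3 / 6,
            ("A", "D"): 4 / 6,
            ("B", "D"): 3 / 6,
            ("A", "B", "D"): 3 / 6,
        }

    def test_single_transaction_full_support(self):
        got = frequent_itemsets(tset([{"A", "B"}]), min_support=1.0)
        flat = {tuple(sorted(s)) for lvl in got.values() for s in lvl}
        assert flat == {("A",), ("B",), ("A", "B")}

    def test_all_fixture_items_survive_3pct(self, fixture_transactions):
        got = frequent_itemsets(fixture_transactions, min_support=0.03, max_size=1)
        assert len(got[1]) == 17  # 16 symptoms + the outcome item
        assert got[1][frozenset({"Obesity=1"})] == 88 / 520  # rarest item

    def test_empty_transaction_set_rejected(self):
        with pytest.raises(MiningError):
            frequent_itemsets(TransactionSet((), frozenset()), 0.5)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(transaction_sets, st.floats(0.05, 1.0))
    def test_exactly_the_supported_itemsets(self, t, min_support):
        # cross-check the level-wise output against direct per-set counting
        got = frequent_itemsets(t, min_support)
        for lvl in got.values():
            for s, supp in lvl.items():
                direct = sum(1 for tr in t.transactions if s <= tr) / t.n
                assert supp == direct
                assert supp >= min_support
        # no frequent set may be missing: check every subset of the universe
        if len(t.item_universe) <= 6:
            from itertools import combinations

            universe = sorted(t.item_universe)
            flat = {s for lvl in got.values() for s in lvl}
            for k in range(1, len(universe) + 1):
                for combo in combinations(universe, k):
                    s = frozenset(combo)
                    direct = sum(1 for tr in t.transactions if s <= tr) / t.n
                    assert (s in flat) == (direct >= min_support)


class TestGenerateRules:
    def test_toy_rule_hand_scored(self, toy_transactions, toy_config):
        rules = mine_rules(toy_transactions, toy_config)
        by_lhs = {r.lhs: r for r in rules}
        r = by_lhs[("A", "B")]
        assert r.rhs == "D"
        assert r.support == 0.5
        assert r.confidence == 1.0
        assert r.lift == pytest.approx(1.2, abs=1e-12)

    def test_fixture_itching_rule_kept_despite_low_lift(self, fixture_transactions):
        rules = mine_rules(fixture_transactions, MiningConfig(max_order=2))
        by_lhs = {r.lhs: r for r in rules}
        r = by_lhs[("Itching=1",)]
        assert r.confidence == pytest.approx(154 / 253)
        assert r.confidence >= 0.60
        assert r.lift_2dp == 0.99  # lift < 1 is reported, never filtered on

    def test_fixture_emits_no_alopecia_rule(self, fixture_transactions):
        rules = mine_rules(fixture_transactions, MiningConfig(max_order=2))
        assert ("Alopecia=1",) not in {r.lhs for r in rules}
        # its confidence 78/179 sits below the 60% threshold
        assert 78 / 179 < 0.60

    def test_absent_target_rejected(self, toy_transactions):
        cfg = MiningConfig(target="Z")
        with pytest.raises(MiningError, match="absent"):
            mine_rules(toy_transactions, cfg)

    def test_general_mode_emits_other_consequents(self, toy_transactions):
        cfg = MiningConfig(min_support=0.3, min_confidence=0.9, target=None)
        rules = mine_rules(toy_transactions, cfg)
        assert {r.rhs for r in rules} > {"D"}

    def test_min_support_above_max_gives_empty(self, toy_transactions):
        cfg = MiningConfig(min_support=0.99, min_confidence=0.6, target="D")
        assert mine_rules(toy_transactions, cfg) == []
        assert brute_force_rules(toy_transactions, cfg) == []


class TestRuleMetricsFromCounts:
    def test_polydipsia_confidence(self):
        s, c, l = rule_metrics_from_counts(TwoByTwo(192, 95, 8, 225))
        assert c == pytest.approx(225 / 233)
        assert round(c, 2) == 0.97

    def test_gender_lift(self):
        s, c, l = rule_metrics_from_counts(TwoByTwo(181, 147, 19, 173))
        assert round(l, 2) == 1.46

    def test_single_cell_table(self):
        s, c, l = rule_metrics_from_counts(TwoByTwo(0, 0, 0, 7))
        assert (s, c, l) == (1.0, 1.0, 1.0)

    def test_zero_exposure_margin_rejected(self):
        with pytest.raises(MiningError):
            rule_metrics_from_counts(TwoByTwo(5, 5, 0, 0))

    def test_matches_transaction_path_on_fixture(
        self, fixture_cohort, fixture_transactions
    ):
        """Order-2 metrics from counts equal the mined raw values exactly."""
        from symmine import crosstab

        rules = mine_rules(fixture_transactions, MiningConfig(max_order=2))
        for r in rules:
            col = r.lhs[0].removesuffix("=1")
            s, c, l = rule_metrics_from_counts(crosstab(fixture_cohort, col))
            assert (r.support, r.confidence, r.lift) == (s, c, l)


class TestRuleInvariants:
    def test_rhs_in_lhs_rejected(self):
        with pytest.raises(ValueError):
            Rule(("A",), "A", 0.5, 0.6, 1.0)

    def test_support_cannot_exceed_confidence(self):
        with pytest.raises(ValueError):
            Rule(("A",), "B", 0.7, 0.6, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(transaction_sets)
    def test_metric_identities_on_mined_rules(self, t):
        target = sorted(t.item_universe)[0] if t.item_universe else None
        if target is None:
            return
        cfg = MiningConfig(min_support=0.1, min_confidence=0.3, target=target)
        rhs_supp = itemset_support({target}, t)
        for r in mine_rules(t, cfg):
            assert r.support <= r.confidence + 1e-15
            # lift * supp(rhs) == confidence, raw values
            assert r.lift * rhs_supp == pytest.approx(r.confidence, abs=1e-12)
            supp_lhs = itemset_support(set(r.lhs), t)
            if r.support == supp_lhs:  # lhs fully implies rhs
                assert r.confidence == 1.0
                assert r.lift == pytest.approx(1.0 / rhs_supp, abs=1e-12)


class TestBruteForceOracle:
    def test_toy_paths_identical(self, toy_transactions, toy_config):
        apriori = mine_rules(toy_transactions, toy_config)
        brute = brute_force_rules(toy_transactions, toy_config)
        assert apriori == brute

    def test_fixture_subset_agrees_rule_for_rule(self, fixture_cohort):
        """Restrict the fixture to 8 symptom columns; enumerate exhaustively."""
        from symmine import Cohort, to_transactions

        keep = [
            "Gender", "Polyuria", "Polydipsia", "weakness",
            "Itching", "Alopecia", "Obesity", "Age", "Diabetes",
        ]
        sub = Cohort(fixture_cohort.data[keep].copy(), "Diabetes")
        t = to_transactions(sub)
        cfg = MiningConfig()  # 3% / 60%, Diabetes=1
        assert mine_rules(t, cfg) == brute_force_rules(t, cfg)

    def test_refuses_oversized_universe(self):
        t = tset([set("ABCDEFGHIJKLMNOP")])  # 16 items
        with pytest.raises(MiningError, match="brute-force limit"):
            brute_force_rules(t, MiningConfig(target="A"))
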