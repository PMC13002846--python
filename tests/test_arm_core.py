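"""Apriori miner vs brute-force oracle, rule metrics, rule generation, ranking."""

import math

import numpy as np
import pytest

from comorbnet.arm_core import (
    AssociationRule,
    FrequentItemset,
    MiningConfig,
    brute_force_frequent,
    generate_rules,
    mine_frequent,
    mine_rules,
    rank_rules,
    round_half_away,
    rule_metrics,
)
from comorbnet.errors import ComorbnetError

from conftest import make_transactions, random_transactions


class TestMineFrequent:
    def test_hand_enumerated_lattice(self, toy_transactions):
        config = MiningConfig(min_support=0.5, max_len=3)
        result = mine_frequent(toy_transactions, config)
        as_dict = {fi.items: fi.support for fi in result}
        assert as_dict == {
            ("A",): 0.75,
            ("B",): 0.75,
            ("C",): 0.75,
            ("A", "B"): 0.5,
            ("A", "C"): 0.5,
            ("B", "C"): 0.5,
        }
        # ordering: size, then descending support, then lexicographic
        assert [fi.items for fi in result] == [
            ("A",), ("B",), ("C",), ("A", "B"), ("A", "C"), ("B", "C"),
        ]

    def test_full_support_threshold_yields_nothing(self, toy_transactions):
        assert mine_frequent(toy_transactions, MiningConfig(min_support=1.0)) == []

    def test_support_count_consistency(self, toy_transactions):
        for fi in mine_frequent(toy_transactions, MiningConfig(min_support=0.25)):
            assert fi.support == pytest.approx(fi.count / toy_transactions.n, abs=1e-12)

    def test_max_len_caps_itemset_size(self, toy_transactions):
        result = mine_frequent(toy_transactions, MiningConfig(min_support=0.25, max_len=2))
        assert max(len(fi.items) for fi in result) == 2

    def test_zero_min_support_rejected(self):
        with pytest.raises(ComorbnetError):
            MiningConfig(min_support=0.0)


class TestBruteForce:
    def test_matches_hand_enumeration(self, toy_transactions):
        config = MiningConfig(min_support=0.5, max_len=3)
        assert brute_force_frequent(toy_transactions, config) == mine_frequent(
            toy_transactions, config
        )

    def test_single_transaction(self):
        ts = make_transactions([{"A"}])
        result = brute_force_frequent(ts, MiningConfig(min_support=0.5))
        assert result == [FrequentItemset(("A",), 1.0, 1)]

    def test_large_universe_guarded(self):
        ts = make_transactions([{f"I{i:02d}" for i in range(21)}])
        with pytest.raises(ComorbnetError, match="guarded"):
            brute_force_frequent(ts, MiningConfig())

    def test_empty_transaction_list_rejected(self):
        ts = make_transactions([])
        with pytest.raises(ComorbnetError):
            brute_force_frequent(ts, MiningConfig())


def test_oracle_equivalence_on_random_instances():
    """Apriori output is identical to exhaustive enumeration on random inputs."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        ts = random_transactions(rng)
        config = MiningConfig(
            min_support=float(rng.uniform(0.1, 0.6)),
            max_len=int(rng.integers(2, 5)),
        )
        assert mine_frequent(ts, config) == brute_force_frequent(ts, config)


def test_downward_closure_on_random_instances():
    """Every subset of a frequent itemset is frequent with >= support."""
    from itertools import combinations

    rng = np.random.default_rng(7)
    for _ in range(100):
        ts = random_transactions(rng, max_txn=20, max_items=6)
        result = mine_frequent(ts, MiningConfig(min_support=0.2, max_len=4))
        supports = {fi.items: fi.support for fi in result}
        for items, support in supports.items():
            for r in range(1, len(items)):
                for sub in combinations(items, r):
                    assert sub in supports
                    assert supports[sub] >= support - 1e-12


class TestRuleMetrics:
    def test_printed_table_anchor_row(self):
        # (B99) -> (B20, B37): s_X=0.34, s_Y=0.40, s=0.22
        m = rule_metrics(0.22, 0.34, 0.40)
        assert round_half_away(m.confidence) == 0.65
        assert round_half_away(m.leverage) == 0.08

    def test_independence_identities(self):
        m = rule_metrics(0.3 * 0.4, 0.3, 0.4)
        assert m.lift == pytest.approx(1.0, abs=1e-12)
        assert m.leverage == pytest.approx(0.0, abs=1e-12)

    def test_perfect_implication_conviction_infinite(self):
        m = rule_metrics(1.0, 1.0, 1.0)
        assert m.confidence == 1.0
        assert math.isinf(m.conviction)

    def test_inconsistent_supports_rejected(self):
        with pytest.raises(ComorbnetError, match="inconsistent"):
            rule_metrics(0.5, 0.3, 0.4)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ComorbnetError):
            rule_metrics(0.0, 0.0, 0.4)


class TestGenerateRules:
    def test_sub_unit_lift_filtered_out(self):
        frequent = [
            FrequentItemset(("A",), 0.75, 3),
            FrequentItemset(("B",), 0.75, 3),
            FrequentItemset(("A", "B"), 0.5, 2),
        ]
        rs = generate_rules(frequent, MiningConfig(min_support=0.5), n=4)
        assert rs.rules == ()  # lift 0.888... < 1

    def test_perfect_cooccurrence_both_directions(self):
        frequent = [
            FrequentItemset(("A",), 0.5, 2),
            FrequentItemset(("B",), 0.5, 2),
            FrequentItemset(("A", "B"), 0.5, 2),
        ]
        rs = generate_rules(frequent, MiningConfig(min_support=0.5), n=4)
        assert {(r.antecedent, r.consequent) for r in rs.rules} == {
            (("A",), ("B",)),
            (("B",), ("A",)),
        }
        for r in rs.rules:
            assert r.confidence == pytest.approx(1.0)
            assert r.lift == pytest.approx(2.0)
            assert math.isinf(r.conviction)

    def test_triple_yields_six_bipartitions(self):
        ts = make_transactions([{"A", "B", "C"}] * 3 + [set()])
        rs = mine_rules(ts, MiningConfig(min_support=0.5))
        triple_rules = [
            r for r in rs.rules if set(r.antecedent) | set(r.consequent) == {"A", "B", "C"}
        ]
        assert len(triple_rules) == 6  # 2^3 - 2 ordered bipartitions


def test_metric_identities_and_symmetry_on_mined_rules():
    """lift = conf/s_Y, leverage = s - s_X s_Y to 1e-12; directions symmetric."""
    rng = np.random.default_rng(99)
    checked = 0
    for _ in range(40):
        ts = random_transactions(rng, max_txn=25, max_items=7)
        rs = mine_rules(ts, MiningConfig(min_support=0.15, min_confidence=0.05, min_lift=0.0))
        by_direction = {}
        for r in rs.rules:
            assert r.lift == pytest.approx(r.confidence / r.support_consequent, abs=1e-12)
            assert r.leverage == pytest.approx(
                r.support - r.support_antecedent * r.support_consequent, abs=1e-12
            )
            if not math.isinf(r.conviction):
                assert r.conviction == pytest.approx(
                    (1 - r.support_consequent) / (1 - r.confidence), abs=1e-12
                )
            assert (r.leverage > 1e-12) == (r.lift > 1 + 1e-12)
            by_direction[(r.antecedent, r.consequent)] = r
            checked += 1
        for (x, y), r in by_direction.items():
            mirror = by_direction.get((y, x))
            if mirror is not None:
                assert r.lift == pytest.approx(mirror.lift, abs=1e-12)
                assert r.leverage == pytest.approx(mirror.leverage, abs=1e-12)
                assert r.support == pytest.approx(mirror.support, abs=1e-12)
    assert checked > 100  # the sweep actually exercised rules


def _rule(ante, cons, support, lift, confidence=0.5):
    return AssociationRule(
        antecedent=ante,
        consequent=cons,
        support_antecedent=0.5,
        support_consequent=0.5,
        support=support,
        confidence=confidence,
        lift=lift,
        leverage=0.01,
        conviction=1.1,
    )


class TestRankRules:
    def _ruleset(self, rules):
        from comorbnet.arm_core import RuleSet

        return RuleSet(rules=tuple(rules), config=MiningConfig(), n=10)

    def test_ranks_by_requested_key(self):
        rs = self._ruleset(
            [_rule(("A",), ("B",), 0.4, 1.2), _rule(("C",), ("D",), 0.3, 1.5)]
        )
        top = rank_rules(rs, key="lift", k=1)
        assert top[0].antecedent == ("C",)

    def test_tie_breaks_lexicographically(self):
        rs = self._ruleset(
            [_rule(("B",), ("C",), 0.4, 1.2), _rule(("A",), ("C",), 0.4, 1.2)]
        )
        assert [r.antecedent for r in rank_rules(rs, key="support")] == [("A",), ("B",)]

    def test_k_larger_than_ruleset(self):
        rs = self._ruleset([_rule(("A",), ("B",), 0.4, 1.2)])
        assert len(rank_rules(rs, key="support", k=10)) == 1

    def test_unknown_key_rejected(self):
        rs = self._ruleset([])
        with pytest.raises(ComorbnetError, match="unknown ranking key"):
            rank_rules(rs, key="leverage")


@pytest.mark.parametrize(
    "value, expected",
    [(0.645, 0.65), (0.055, 0.06), (0.0716, 0.07), (-0.055, -0.06), (0.41509, 0.42)],
)
def test_round_half_away(value, expected):
    assert round_half_away(value) == expected
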