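from __future__ import annotations

import math

import numpy as np
import pytest

from subsetbind.binding import (
    BindingConfig,
    BindingRule,
    bind,
    joint_support,
    rule_metrics,
)
from subsetbind.fuzzify import FuzzyItem, MembershipTable
from subsetbind.mining import FuzzyItemset, MiningConfig, mine_frequent_itemsets

from conftest import crisp_table, random_membership_table


def _pair_of_tables():
    obs = ("o0", "o1", "o2", "o3")
    t1 = MembershipTable(obs, (FuzzyItem("X", None),),
                         np.array([[1.0], [0.5], [0.0], [1.0]]))
    t2 = MembershipTable(obs, (FuzzyItem("Y", None),),
                         np.array([[0.5], [0.5], [1.0], [0.0]]))
    return t1, t2


class TestJointSupport:
    def test_worked_example(self):
        t1, t2 = _pair_of_tables()
        assert joint_support(t1, t2, ["X"], ["Y"]) == pytest.approx(0.25)

    def test_universal_consequent_reduces_to_antecedent_support(self):
        t1, t2 = _pair_of_tables()
        t2_ones = MembershipTable(t2.observation_ids, t2.items, np.ones((4, 1)))
        assert joint_support(t1, t2_ones, ["X"], ["Y"]) == pytest.approx(0.625)

    def test_bounded_by_marginals(self, rng):
        t1 = random_membership_table(rng, 15, 2, 1)
        t2 = random_membership_table(rng, 15, 1, 2)
        x = list(t1.item_ids)[:2]
        y = list(t2.item_ids)[:2]
        sj = joint_support(t1, t2, x, y)
        sx = float(t1.columns(x).min(axis=1).mean())
        sy = float(t2.columns(y).min(axis=1).mean())
        assert sj <= min(sx, sy) + 1e-12

    def test_misaligned_observations_rejected(self):
        t1, t2 = _pair_of_tables()
        shuffled = MembershipTable(("o3", "o1", "o2", "o0"), t2.items, t2.values)
        with pytest.raises(ValueError, match="align by id"):
            joint_support(t1, shuffled, ["X"], ["Y"])


class TestRuleMetrics:
    def test_worked_example(self):
        conf, lift, conv = rule_metrics(0.25, 0.625, 0.5)
        assert conf == pytest.approx(0.4)
        assert lift == pytest.approx(0.8)
        assert conv == pytest.approx(0.5 / 0.6)

    def test_independent_crisp_sides_have_lift_one(self):
        conf, lift, conv = rule_metrics(0.25, 0.5, 0.5)
        assert lift == pytest.approx(1.0)

    def test_perfect_implication_has_infinite_conviction(self):
        conf, lift, conv = rule_metrics(0.5, 0.5, 0.5)
        assert conf == 1.0
        assert math.isinf(conv)

    def test_universal_consequent_conviction_is_one(self):
        _, _, conv = rule_metrics(0.5, 0.5, 1.0)
        assert conv == 1.0

    def test_zero_antecedent_support_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rule_metrics(0.1, 0.0, 0.5)


class TestBind:
    def test_low_lift_rule_pruned(self):
        t1, t2 = _pair_of_tables()
        fis1 = [FuzzyItemset(("X",), 0.625)]
        fis2 = [FuzzyItemset(("Y",), 0.5)]
        cfg = BindingConfig(min_lift=2.0)
        assert bind(fis1, fis2, t1, t2, cfg) == []

    def test_perfectly_nested_pattern_retained_with_lift_inverse_rho(self):
        # X(a) = Y(a) = 1 on 30% of observations: lift = 1/0.3
        m = 10
        obs = tuple(f"o{i}" for i in range(m))
        col = np.zeros((m, 1))
        col[:3] = 1.0
        t1 = MembershipTable(obs, (FuzzyItem("X", None),), col)
        t2 = MembershipTable(obs, (FuzzyItem("Y", None),), col.copy())
        fis1 = [FuzzyItemset(("X",), 0.3)]
        fis2 = [FuzzyItemset(("Y",), 0.3)]
        rules = bind(fis1, fis2, t1, t2, BindingConfig(min_lift=2.0))
        assert len(rules) == 1
        assert rules[0].lift == pytest.approx(1 / 0.3)

    def test_both_directions_share_lift_but_not_confidence(self, rng):
        t1 = crisp_table(rng, 30, 2, rate=0.5)
        t2 = crisp_table(rng, 30, 2, rate=0.5)
        t2 = MembershipTable(t1.observation_ids,
                             tuple(FuzzyItem(f"c{j}", None) for j in range(2)),
                             t2.values)
        fis1 = mine_frequent_itemsets(t1, MiningConfig(min_support=0.05))
        fis2 = mine_frequent_itemsets(t2, MiningConfig(min_support=0.05))
        rules = bind(fis1, fis2, t1, t2,
                     BindingConfig(min_lift=0.01, direction="both"))
        fwd = {(r.antecedent, r.consequent): r for r in rules if r.direction == "1->2"}
        rev = {(r.consequent, r.antecedent): r for r in rules if r.direction == "2->1"}
        assert set(fwd) == set(rev)
        for key, r in fwd.items():
            mirror = rev[key]
            assert mirror.lift == pytest.approx(r.lift, abs=1e-12)
            assert mirror.support_joint == pytest.approx(r.support_joint, abs=1e-12)
            assert mirror.confidence == pytest.approx(
                r.support_joint / r.support_consequent, abs=1e-12)

    def test_metrics_reproducible_from_stored_supports(self, rng):
        t1 = random_membership_table(rng, 25, 2, 2)
        t2 = random_membership_table(rng, 25, 1, 3)
        t2 = MembershipTable(t1.observation_ids, t2.items, t2.values)
        fis1 = mine_frequent_itemsets(t1, MiningConfig(min_support=0.05))
        fis2 = mine_frequent_itemsets(t2, MiningConfig(min_support=0.05))
        rules = bind(fis1, fis2, t1, t2, BindingConfig(min_lift=0.5))
        assert rules
        for r in rules:
            conf, lift, conv = rule_metrics(
                r.support_joint, r.support_antecedent, r.support_consequent)
            assert r.confidence == pytest.approx(conf, abs=1e-12)
            assert r.lift == pytest.approx(lift, abs=1e-12)
            assert r.conviction == conv or r.conviction == pytest.approx(conv, abs=1e-12)

    def test_raising_min_lift_never_adds_rules(self, rng):
        t1 = crisp_table(rng, 40, 3)
        t2 = crisp_table(rng, 40, 3)
        t2 = MembershipTable(t1.observation_ids,
                             tuple(FuzzyItem(f"c{j}", None) for j in range(3)),
                             t2.values)
        fis1 = mine_frequent_itemsets(t1, MiningConfig(min_support=0.05))
        fis2 = mine_frequent_itemsets(t2, MiningConfig(min_support=0.05))
        keys = None
        for lift_min in (0.1, 0.5, 1.0, 2.0):
            rules = bind(fis1, fis2, t1, t2, BindingConfig(min_lift=lift_min))
            new = {(r.antecedent, r.consequent) for r in rules}
            if keys is not None:
                assert new <= keys
            keys = new

    def test_crisp_lift_matches_contingency_tabulation(self, rng):
        t1 = crisp_table(rng, 50, 2, rate=0.5)
        t2 = crisp_table(rng, 50, 2, rate=0.5)
        t2 = MembershipTable(t1.observation_ids,
                             tuple(FuzzyItem(f"c{j}", None) for j in range(2)),
                             t2.values)
        fis1 = mine_frequent_itemsets(t1, MiningConfig(min_support=0.05, max_items=1))
        fis2 = mine_frequent_itemsets(t2, MiningConfig(min_support=0.05, max_items=1))
        rules = bind(fis1, fis2, t1, t2, BindingConfig(min_lift=0.01))
        for r in rules:
            x = t1.column(r.antecedent[0]).astype(bool)
            y = t2.column(r.consequent[0]).astype(bool)
            pxy = (x & y).mean()
            expected = pxy / (x.mean() * y.mean())
            assert r.lift == pytest.approx(expected, abs=1e-12)

    def test_empty_side_warns(self, rng):
        t1 = crisp_table(rng, 10, 2)
        t2 = crisp_table(rng, 10, 2)
        t2 = MembershipTable(t1.observation_ids, t2.items, t2.values)
        with pytest.warns(UserWarning, match="no rules"):
            assert bind([], [FuzzyItemset(("b0",), 0.5)], t1, t2,
                        BindingConfig(min_lift=1.0)) == []

    def test_rules_sorted_by_lift_then_support(self, rng):
        t1 = crisp_table(rng, 40, 3)
        t2 = crisp_table(rng, 40, 3)
        t2 = MembershipTable(t1.observation_ids,
                             tuple(FuzzyItem(f"c{j}", None) for j in range(3)),
                             t2.values)
        fis1 = mine_frequent_itemsets(t1, MiningConfig(min_support=0.05))
        fis2 = mine_frequent_itemsets(t2, MiningConfig(min_support=0.05))
        rules = bind(fis1, fis2, t1, t2, BindingConfig(min_lift=0.1))
        keys = [(-r.lift, -r.support_joint, r.antecedent, r.consequent) for r in rules]
        assert keys == sorted(keys)


def test_binding_config_requires_a_threshold():
    with pytest.raises(ValueError, match="at least one"):
        BindingConfig()


def test_rule_invariant_joint_bounded():
    with pytest.raises(ValueError, match="exceeds"):
        BindingRule("1->2", ("a",), ("b",), 0.2, 0.2, 0.5, 1.0, 1.0, 1.0)
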