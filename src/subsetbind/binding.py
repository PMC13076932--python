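"""Cross-dataset rule generation ("binding") and rule metrics.

Antecedents come from one dataset's frequent itemsets and consequents
from the other's, so each retained rule links a clinical pattern to an
omics pattern (or vice versa) over the same ordered observations.
Rules are scored with the fuzzy support of the combined sides and the
standard association-rule metrics derived from it:

    support(X -> Y)    = (1/m) sum_a min(X(a), Y(a))
    confidence(X -> Y) = support(X -> Y) / support(X)
    lift(X -> Y)       = support(X -> Y) / (support(X) * support(Y))
    conviction(X -> Y) = (1 - support(Y)) / (1 - confidence(X -> Y))

where X(a) is the min membership over X's items in observation a.
Lift is 1 under independence and symmetric in the two sides;
confidence and conviction are directional.  Conviction diverges to
+infinity as a rule approaches a perfect implication.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, model_validator

from .fuzzify import MembershipTable
from .mining import FuzzyItemset

__all__ = ["BindingRule", "BindingConfig", "joint_support", "rule_metrics", "bind"]

Direction = Literal["1->2", "2->1"]


@dataclass(frozen=True)
class BindingRule:
    """One cross-dataset association rule with its stored supports and
    the metrics derived from them.

    ``direction`` records which dataset supplied the antecedent; the
    items themselves are sorted tuples of item ids.
    """

    direction: Direction
    antecedent: tuple[str, ...]
    consequent: tuple[str, ...]
    support_antecedent: float
    support_consequent: float
    support_joint: float
    confidence: float
    lift: float
    conviction: float  # may be math.inf

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("rule sides must be non-empty")
        if self.support_joint > min(self.support_antecedent, self.support_consequent) + 1e-12:
            raise ValueError("joint support exceeds a marginal support")

    @property
    def items(self) -> tuple[str, ...]:
        """All item ids on both sides (antecedent then consequent)."""
        return self.antecedent + self.consequent


class BindingConfig(BaseModel):
    """Rule-pruning thresholds; at least one must be set.

    ``direction`` selects which dataset supplies antecedents ("1->2",
    "2->1") or both.
    """

    min_lift: float | None = None
    min_confidence: float | None = None
    min_conviction: float | None = None
    direction: Literal["1->2", "2->1", "both"] = "1->2"

    @model_validator(mode="after")
    def _at_least_one(self) -> "BindingConfig":
        if self.min_lift is None and self.min_confidence is None and self.min_conviction is None:
            raise ValueError("at least one pruning threshold must be set")
        if self.min_confidence is not None and not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must lie in [0, 1]")
        return self


def _side_membership(table: MembershipTable, items: Sequence[str]) -> np.ndarray:
    return table.columns(tuple(items)).min(axis=1)


def joint_support(
    table1: MembershipTable,
    table2: MembershipTable,
    x_items: Sequence[str],
    y_items: Sequence[str],
) -> float:
    """Fuzzy support of X -> Y across the paired tables.

    X(a) and Y(a) are each the min membership over their items; the
    joint support is the mean of min(X(a), Y(a)).  The tables must
    describe the same observations in the same order — that pairing is
    what makes a cross-dataset rule meaningful.
    """
    if table1.observation_ids != table2.observation_ids:
        raise ValueError(
            "paired tables must share observation ids and order; align by id first"
        )
    x = _side_membership(table1, x_items)
    y = _side_membership(table2, y_items)
    return float(np.minimum(x, y).mean())


def rule_metrics(
    support_joint: float, support_x: float, support_y: float
) -> tuple[float, float, float]:
    """(confidence, lift, conviction) from the three stored supports.

    Conviction is +infinity at confidence 1 with support(Y) < 1 (a
    perfect implication of a non-trivial consequent) and 1 when the
    consequent itself is universal.
    """
    if support_x <= 0.0:
        raise ValueError("antecedent support must be positive")
    confidence = support_joint / support_x
    lift = support_joint / (support_x * support_y) if support_y > 0 else 0.0
    if confidence >= 1.0:
        conviction = 1.0 if support_y >= 1.0 else math.inf
    else:
        conviction = (1.0 - support_y) / (1.0 - confidence)
    return confidence, lift, conviction


def _passes(conf: float, lift: float, conv: float, config: BindingConfig) -> bool:
    if config.min_lift is not None and lift < config.min_lift:
        return False
    if config.min_confidence is not None and conf < config.min_confidence:
        return False
    if config.min_conviction is not None and conv < config.min_conviction:
        return False
    return True


def bind(
    fis1: Sequence[FuzzyItemset],
    fis2: Sequence[FuzzyItemset],
    table1: MembershipTable,
    table2: MembershipTable,
    config: BindingConfig,
) -> list[BindingRule]:
    """Evaluate the cross product of frequent itemsets from the two
    datasets and keep every rule passing all configured thresholds.

    Output is sorted by (lift desc, joint support desc, antecedent,
    consequent).  Both itemset lists are assumed to already satisfy
    their dataset's min_support/min_items filters (that is the
    mechanism limiting the cross product).
    """
    if table1.observation_ids != table2.observation_ids:
        raise ValueError(
            "paired tables must share observation ids and order; align by id first"
        )
    if not fis1 or not fis2:
        warnings.warn("empty frequent-itemset list on one side; no rules generated",
                      stacklevel=2)
        return []

    mem1 = {f.items: _side_membership(table1, f.items) for f in fis1}
    mem2 = {f.items: _side_membership(table2, f.items) for f in fis2}

    rules: list[BindingRule] = []
    directions: list[Direction] = (
        ["1->2", "2->1"] if config.direction == "both" else [config.direction]
    )
    for f1 in fis1:
        v1 = mem1[f1.items]
        for f2 in fis2:
            v2 = mem2[f2.items]
            sj = float(np.minimum(v1, v2).mean())
            for direction in directions:
                if direction == "1->2":
                    ant, cons, sa, sc = f1, f2, f1.support, f2.support
                else:
                    ant, cons, sa, sc = f2, f1, f2.support, f1.support
                conf, lift, conv = rule_metrics(sj, sa, sc)
                if _passes(conf, lift, conv, config):
                    rules.append(
                        BindingRule(
                            direction=direction,
                            antecedent=ant.items,
                            consequent=cons.items,
                            support_antecedent=sa,
                            support_consequent=sc,
                            support_joint=sj,
                            confidence=conf,
                            lift=lift,
                            conviction=conv,
                        )
                    )
    rules.sort(key=lambda r: (-r.lift, -r.support_joint, r.antecedent, r.consequent))
    return rules
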