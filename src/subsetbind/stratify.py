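"""Combining rule sets across clinical categories and flagging core features.

The cross-dataset rules from each clinical category (e.g. medical
records, CT interpretation reports, blood tests) are scanned for
user-designated disease-characteristic target items; every feature
(e.g. protein) that appears on the feature side of at least one rule
whose clinical side contains a target item of a category counts as
*linked* to that category.  Features linked to two or more categories
are flagged as core features ("core molecules").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from pydantic import BaseModel

from .binding import BindingRule
from .fuzzify import ITEM_SEP

__all__ = ["TargetItem", "TargetItemList", "LinkedFeatureReport", "select_linked_features"]

CORE_MIN_CATEGORIES = 2


class TargetItem(BaseModel):
    """A disease-characteristic clinical attribute with the membership
    side that marks it (``Low``/``High`` for fuzzified attributes, a
    level name for categoricals, or ``any`` as a wildcard)."""

    attribute: str
    side: str = "any"


class TargetItemList(BaseModel):
    """The target items of one clinical category."""

    category: str
    items: tuple[TargetItem, ...]


@dataclass(frozen=True)
class LinkedFeatureReport:
    """Per-feature linkage across clinical categories."""

    feature: str
    linked_categories: tuple[str, ...]

    @property
    def category_count(self) -> int:
        return len(self.linked_categories)

    @property
    def core(self) -> bool:
        return self.category_count >= CORE_MIN_CATEGORIES


def _matches(item_id: str, target: TargetItem) -> bool:
    if ITEM_SEP in item_id:
        attribute, category = item_id.rsplit(ITEM_SEP, 1)
    else:
        attribute, category = item_id, None
    if attribute != target.attribute:
        return False
    return target.side == "any" or category == target.side


def _split_sides(
    rule: BindingRule, feature_side: str
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(feature items, clinical items) of a rule given which dataset
    label holds the features."""
    ant_dataset = rule.direction[0]  # "1" or "2"
    if ant_dataset == feature_side:
        return rule.antecedent, rule.consequent
    return rule.consequent, rule.antecedent


def select_linked_features(
    rule_sets: Mapping[str, Sequence[BindingRule]],
    targets: Sequence[TargetItemList],
    feature_side: Literal["1", "2"] = "2",
) -> list[LinkedFeatureReport]:
    """Select features linked to target items, per clinical category.

    A feature is linked to a category iff it appears on the feature
    side of at least one of that category's rules whose clinical side
    contains at least one of the category's target items.  The report
    is sorted by (category count desc, feature id); features linked to
    no category are omitted.
    """
    known = set(rule_sets)
    for t in targets:
        if t.category not in known:
            raise ValueError(
                f"targets reference unknown category {t.category!r}; "
                f"rule sets cover {sorted(known)!r}"
            )

    linked: dict[str, set[str]] = {}
    for tlist in targets:
        for rule in rule_sets[tlist.category]:
            feat_items, clin_items = _split_sides(rule, feature_side)
            if any(_matches(c, t) for c in clin_items for t in tlist.items):
                for f in feat_items:
                    linked.setdefault(f, set()).add(tlist.category)

    reports = [
        LinkedFeatureReport(feature=f, linked_categories=tuple(sorted(cats)))
        for f, cats in linked.items()
    ]
    reports.sort(key=lambda r: (-r.category_count, r.feature))
    return reports
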