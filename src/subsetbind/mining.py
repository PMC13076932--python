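"""Fuzzy Apriori mining of frequent itemsets in one membership table.

The support of an itemset S is the mean over observations of the
min-combined membership of its items, ``(1/m) * sum_a min_{i in S}
mu_i(a)``.  With 0/1 memberships this reduces to the classical relative
co-occurrence frequency.  The min t-norm makes support anti-monotone
(a superset can never be more frequent than a subset), which the
levelwise Apriori search exploits for pruning.

Itemsets never combine the Low and High sides of the same attribute:
under z-score fuzzification their joint membership is identically zero
and the resulting itemset would be uninterpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel, model_validator

from .fuzzify import MembershipTable

__all__ = ["FuzzyItemset", "MiningConfig", "itemset_support", "mine_frequent_itemsets"]


@dataclass(frozen=True)
class FuzzyItemset:
    """A sorted tuple of item ids from one dataset with its fuzzy support."""

    items: tuple[str, ...]
    support: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if not self.items:
            raise ValueError("itemset must be non-empty")
        if tuple(sorted(self.items)) != self.items:
            raise ValueError("itemset items must be sorted")
        if not 0.0 <= self.support <= 1.0:
            raise ValueError("support must lie in [0, 1]")

    @property
    def size(self) -> int:
        return len(self.items)


class MiningConfig(BaseModel):
    """Apriori thresholds.

    ``min_support`` is the fuzzy-support floor in (0, 1]; ``min_items``
    and ``max_items`` bound the *reported* itemset sizes (growth always
    starts from singletons).  ``max_items=None`` means unbounded: the
    search terminates naturally when no candidate survives.
    """

    min_support: float
    min_items: int = 1
    max_items: int | None = None

    @model_validator(mode="after")
    def _check(self) -> "MiningConfig":
        if not 0.0 < self.min_support <= 1.0:
            raise ValueError("min_support must lie in (0, 1]")
        if self.min_items < 1:
            raise ValueError("min_items must be >= 1")
        if self.max_items is not None and self.max_items < self.min_items:
            raise ValueError("max_items must be >= min_items")
        return self


def itemset_support(table: MembershipTable, items: Iterable[str]) -> float:
    """Fuzzy support of an itemset: mean over observations of the min
    membership across its items."""
    ids = tuple(items)
    if not ids:
        raise ValueError("support of the empty itemset is undefined")
    return float(table.columns(ids).min(axis=1).mean())


def _candidates(
    frequent_k: Sequence[tuple[str, ...]],
    frequent_set: set[tuple[str, ...]],
    attr_of: dict[str, str],
) -> list[tuple[str, ...]]:
    """Classical Apriori-gen: join k-itemsets sharing a (k-1)-prefix in
    lexicographic order, then prune candidates with an infrequent
    (k-1)-subset or a same-attribute item pair."""
    out: list[tuple[str, ...]] = []
    n = len(frequent_k)
    for i in range(n):
        a = frequent_k[i]
        for j in range(i + 1, n):
            b = frequent_k[j]
            if a[:-1] != b[:-1]:
                break  # sorted list: no further shared prefix
            last_a, last_b = a[-1], b[-1]
            if attr_of[last_a] == attr_of[last_b]:
                continue
            cand = a + (last_b,)
            # every (k)-subset must itself be frequent
            if all(
                cand[:s] + cand[s + 1:] in frequent_set for s in range(len(cand) - 2)
            ):
                out.append(cand)
    return out


def mine_frequent_itemsets(
    table: MembershipTable, config: MiningConfig
) -> list[FuzzyItemset]:
    """Levelwise fuzzy Apriori.

    Returns every admissible itemset S (no same-attribute Low/High
    pair) with ``min_items <= |S| <= max_items`` and ``support(S) >=
    min_support``, sorted by (size, support descending, lexicographic
    items), with exact supports attached.
    """
    if len(table.items) == 0:
        warnings.warn("membership table has no items; nothing to mine", stacklevel=2)
        return []
    attr_of = {iid: table.attribute_of(iid) for iid in table.item_ids}

    # level 1
    ids = sorted(table.item_ids)
    vectors: dict[tuple[str, ...], np.ndarray] = {}
    supports: dict[tuple[str, ...], float] = {}
    level: list[tuple[str, ...]] = []
    for iid in ids:
        col = table.column(iid)
        s = float(col.mean())
        if s >= config.min_support:
            key = (iid,)
            level.append(key)
            vectors[key] = col
            supports[key] = s

    results: list[FuzzyItemset] = []
    k = 1
    while level:
        if config.min_items <= k and (config.max_items is None or k <= config.max_items):
            results.extend(FuzzyItemset(s, supports[s]) for s in level)
        if config.max_items is not None and k >= config.max_items:
            break
        frequent_set = set(level)
        next_level: list[tuple[str, ...]] = []
        next_vectors: dict[tuple[str, ...], np.ndarray] = {}
        for cand in _candidates(level, frequent_set, attr_of):
            vec = np.minimum(vectors[cand[:-1]], vectors[(cand[-1],)])
            s = float(vec.mean())
            if s >= config.min_support:
                next_level.append(cand)
                next_vectors[cand] = vec
                supports[cand] = s
        # keep singleton vectors for future joins
        next_vectors.update({key: vectors[key] for key in vectors if len(key) == 1})
        vectors = next_vectors
        level = next_level
        k += 1

    results.sort(key=lambda f: (f.size, -f.support, f.items))
    return results
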