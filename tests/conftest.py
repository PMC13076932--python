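from __future__ import annotations

import numpy as np
import pytest

from subsetbind.fuzzify import FuzzyItem, MembershipTable, zscore_membership


def random_membership_table(
    rng: np.random.Generator,
    m: int,
    n_quant: int,
    n_binary: int,
    binary_rate: float = 0.4,
) -> MembershipTable:
    """A mixed crisp/fuzzy table: quantitative attributes contribute
    z-score Low/High item pairs, binary attributes crisp 0/1 items."""
    items: list[FuzzyItem] = []
    cols: list[np.ndarray] = []
    for q in range(n_quant):
        low, high = zscore_membership(rng.standard_normal(m))
        items += [FuzzyItem(f"q{q}", "Low"), FuzzyItem(f"q{q}", "High")]
        cols += [low, high]
    for b in range(n_binary):
        items.append(FuzzyItem(f"b{b}", None))
        cols.append((rng.random(m) < binary_rate).astype(float))
    obs = tuple(f"o{i}" for i in range(m))
    return MembershipTable(obs, tuple(items), np.column_stack(cols))


def crisp_table(rng: np.random.Generator, m: int, n_items: int,
                rate: float = 0.4) -> MembershipTable:
    items = tuple(FuzzyItem(f"b{j}", None) for j in range(n_items))
    values = (rng.random((m, n_items)) < rate).astype(float)
    return MembershipTable(tuple(f"o{i}" for i in range(m)), items, values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table() -> MembershipTable:
    """The worked four-observation example: A = [1, .5, 0, 1],
    B = [.5, .5, 1, 0]."""
    items = (FuzzyItem("A", None), FuzzyItem("B", None))
    values = np.array([[1.0, 0.5], [0.5, 0.5], [0.0, 1.0], [1.0, 0.0]])
    return MembershipTable(("o0", "o1", "o2", "o3"), items, values)
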