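"""Independent reference implementations used only by the tests.

Everything here is deliberately naive — plain Python loops over
exhaustively enumerated combinations — and shares no code with the
package, so it can serve as an oracle for the levelwise miner and the
rule metrics.
"""

from __future__ import annotations

import itertools
from typing import Sequence


def naive_itemset_support(rows: Sequence[Sequence[float]], cols: Sequence[int]) -> float:
    """Mean over rows of the min membership across the given columns."""
    total = 0.0
    for row in rows:
        total += min(row[c] for c in cols)
    return total / len(rows)


def enumerate_frequent_itemsets(
    rows: Sequence[Sequence[float]],
    item_ids: Sequence[str],
    attribute_of: dict[str, str],
    min_support: float,
    min_items: int = 1,
    max_items: int | None = None,
) -> dict[tuple[str, ...], float]:
    """Exhaustively enumerate every admissible itemset with support >=
    min_support (no Low/High pair of the same attribute, sizes within
    [min_items, max_items])."""
    order = sorted(range(len(item_ids)), key=lambda i: item_ids[i])
    n = len(item_ids)
    top = n if max_items is None else min(n, max_items)
    out: dict[tuple[str, ...], float] = {}
    for k in range(max(1, min_items), top + 1):
        for combo in itertools.combinations(order, k):
            attrs = [attribute_of[item_ids[c]] for c in combo]
            if len(set(attrs)) != len(attrs):
                continue
            s = naive_itemset_support(rows, combo)
            if s >= min_support:
                out[tuple(item_ids[c] for c in combo)] = s
    return out


def crisp_cooccurrence(rows: Sequence[Sequence[float]], cols: Sequence[int]) -> float:
    """Classical relative co-occurrence frequency on 0/1 transactions."""
    hits = sum(1 for row in rows if all(row[c] == 1 for c in cols))
    return hits / len(rows)
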