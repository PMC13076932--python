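"""Fuzzification of mixed clinical/omics matrices into membership tables.

Quantitative attributes are expanded into two fuzzy categorical items,
``<attr>__Low`` and ``<attr>__High``, whose per-observation membership
grades in [0, 1] express how far below or above the column's typical
value an observation sits.  Binary indicator columns pass through as
single crisp items, and categorical columns are one-hot expanded into
one crisp item per declared level.

Two membership functions are provided:

* **z-score conversion** — the column is standardised, divided by 2 and
  clamped to [-1, 1]; the positive part is the High membership and the
  negated negative part the Low membership, so ``Low * High == 0`` and
  ``Low + High <= 1`` always hold.
* **histogram conversion** — an equal-width histogram locates the modal
  bin; memberships ramp linearly from the modal bin centre out to the
  column minimum (Low) and maximum (High).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

__all__ = [
    "ColumnSchema",
    "FuzzyItem",
    "MembershipTable",
    "HistogramMembershipParams",
    "zscore_membership",
    "fit_histogram_params",
    "histogram_membership",
    "fuzzify_matrix",
]

ITEM_SEP = "__"


class ColumnSchema(BaseModel):
    """Declared type of one input column.

    ``kind`` is one of ``quantitative`` (real-valued, gets fuzzified),
    ``binary`` (crisp 0/1 indicator) or ``categorical`` (values drawn
    from the declared ``levels``, one-hot expanded).
    """

    attribute: str
    kind: Literal["quantitative", "binary", "categorical"]
    levels: tuple[str, ...] = ()

    @field_validator("attribute")
    @classmethod
    def _no_separator(cls, v: str) -> str:
        if not v:
            raise ValueError("attribute name must be non-empty")
        if ITEM_SEP in v:
            raise ValueError(
                f"attribute name {v!r} may not contain {ITEM_SEP!r}: it is "
                "reserved as the item-name separator"
            )
        return v

    @model_validator(mode="after")
    def _levels_only_categorical(self) -> "ColumnSchema":
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise ValueError(
                    f"categorical attribute {self.attribute!r} needs >= 2 levels"
                )
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(
                    f"categorical attribute {self.attribute!r} has duplicate levels"
                )
        elif self.levels:
            raise ValueError(
                f"{self.kind} attribute {self.attribute!r} must not declare levels"
            )
        return self


@dataclass(frozen=True)
class FuzzyItem:
    """One (attribute, category) pair; category ``None`` marks a crisp
    binary passthrough item whose id is the bare attribute name."""

    attribute: str
    category: str | None = None

    @property
    def item_id(self) -> str:
        if self.category is None:
            return self.attribute
        return f"{self.attribute}{ITEM_SEP}{self.category}"

    @staticmethod
    def from_id(item_id: str) -> "FuzzyItem":
        if ITEM_SEP in item_id:
            attribute, category = item_id.rsplit(ITEM_SEP, 1)
            return FuzzyItem(attribute, category)
        return FuzzyItem(item_id, None)


@dataclass
class MembershipTable:
    """Fuzzified matrix: m observations x n items, memberships in [0, 1].

    Row order is identical to the source matrix; item order is the
    deterministic schema order with Low before High.
    """

    observation_ids: tuple[str, ...]
    items: tuple[FuzzyItem, ...]
    values: np.ndarray  # shape (m, n_items), float64

    def __post_init__(self) -> None:
        self.observation_ids = tuple(str(o) for o in self.observation_ids)
        self.items = tuple(self.items)
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape
        if m != len(self.observation_ids) or n != len(self.items):
            raise ValueError("values shape does not match ids/items")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in membership table")
        if np.isnan(self.values).any():
            raise ValueError("membership values contain NaN")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("membership values must lie in [0, 1]")
        self._index = {iid: j for j, iid in enumerate(ids)}

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def attribute_of(self, item_id: str) -> str:
        return self.items[self._index[item_id]].attribute

    def column(self, item_id: str) -> np.ndarray:
        try:
            return self.values[:, self._index[item_id]]
        except KeyError:
            raise KeyError(f"unknown item {item_id!r}") from None

    def columns(self, item_ids: Sequence[str]) -> np.ndarray:
        return np.column_stack([self.column(i) for i in item_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.observation_ids), columns=list(self.item_ids)
        )

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> "MembershipTable":
        items = tuple(FuzzyItem.from_id(c) for c in frame.columns)
        return MembershipTable(
            tuple(str(i) for i in frame.index), items, frame.to_numpy(dtype=float)
        )


@dataclass
class HistogramMembershipParams:
    """Fitted anchors of the histogram membership function for one column."""

    n_bins: int
    bin_edges: np.ndarray = field(default_factory=lambda: np.empty(0))
    frequencies: np.ndarray = field(default_factory=lambda: np.empty(0))
    modal_index: int = 0

    @property
    def modal_center(self) -> float:
        return 0.5 * (self.bin_edges[self.modal_index] + self.bin_edges[self.modal_index + 1])


def _check_column(column: np.ndarray, what: str) -> np.ndarray:
    col = np.asarray(column, dtype=float)
    if col.ndim != 1:
        raise ValueError(f"{what}: expected a 1-D column")
    if not np.isfinite(col).all():
        raise ValueError(
            f"{what}: missing/non-finite values present; impute upstream before "
            "fuzzification"
        )
    return col


def zscore_membership(
    column: np.ndarray, *, ddof: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score membership conversion for one quantitative column.

    z-scores (population sd by default, ``ddof`` configurable) are
    divided by 2 and clamped to [-1, 1]; High is the positive part and
    Low the negated negative part, so the two categories oppose each
    other exactly.

    Returns ``(low, high)``, each in [0, 1]^m.  A constant column
    carries no Low/High information and yields all-zero memberships
    with a warning.
    """
    col = _check_column(column, "zscore_membership")
    if col.size < 2:
        raise ValueError("zscore_membership: need at least 2 observations")
    sd = col.std(ddof=ddof)
    if sd == 0.0:
        warnings.warn(
            "constant column: no Low/High gradation exists, memberships set to 0",
            stacklevel=2,
        )
        z = np.zeros_like(col)
    else:
        z = (col - col.mean()) / sd
    v = np.clip(z / 2.0, -1.0, 1.0)
    return np.maximum(-v, 0.0), np.maximum(v, 0.0)


def fit_histogram_params(column: np.ndarray, n_bins: int = 5) -> HistogramMembershipParams:
    """Fit equal-width histogram anchors over [min, max] for one column.

    Ties for the modal bin are broken toward the lowest bin index.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    col = _check_column(column, "fit_histogram_params")
    edges = np.linspace(col.min(), col.max(), n_bins + 1)
    freqs, _ = np.histogram(col, bins=edges)
    modal = int(np.argmax(freqs))  # argmax takes the lowest index on ties
    return HistogramMembershipParams(n_bins, edges, freqs.astype(float), modal)


def histogram_membership(
    column: np.ndarray,
    params: HistogramMembershipParams | None = None,
    *,
    n_bins: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram-based membership conversion for one quantitative column.

    An equal-width histogram locates the modal bin; with modal bin
    centre ``c``, ``low(a) = clamp((c - x(a)) / (c - min), 0, 1)`` and
    ``high(a) = clamp((x(a) - c) / (max - c), 0, 1)``.  Values at the
    modal centre anchor both ramps at zero.  When the modal bin sits at
    an extreme of the range, the vanished side is all-zero (warned).
    """
    col = _check_column(column, "histogram_membership")
    if col.min() == col.max():
        warnings.warn(
            "constant column: no Low/High gradation exists, memberships set to 0",
            stacklevel=2,
        )
        z = np.zeros_like(col)
        return z, z.copy()
    if params is None:
        params = fit_histogram_params(col, n_bins)
    c = params.modal_center
    lo, hi = col.min(), col.max()
    low = np.zeros_like(col)
    high = np.zeros_like(col)
    if c > lo:
        low = np.clip((c - col) / (c - lo), 0.0, 1.0)
    else:
        warnings.warn("modal bin at the column minimum: Low memberships all zero",
                      stacklevel=2)
    if c < hi:
        high = np.clip((col - c) / (hi - c), 0.0, 1.0)
    else:
        warnings.warn("modal bin at the column maximum: High memberships all zero",
                      stacklevel=2)
    return low, high


def fuzzify_matrix(
    matrix: pd.DataFrame,
    schema: Sequence[ColumnSchema],
    method: Literal["zscore", "histogram"] = "zscore",
    *,
    n_bins: int = 5,
    ddof: int = 0,
    log2_transform: bool = False,
) -> MembershipTable:
    """Fuzzify a matrix according to its column schema.

    Quantitative columns become ``attr__Low``/``attr__High`` item pairs
    via the chosen membership function; binary columns pass through as
    single crisp items; categorical columns are one-hot expanded into
    crisp ``attr__<level>`` items.  Item order follows the schema, Low
    before High.  ``log2_transform`` applies log2 to quantitative
    columns (all values must be positive) before conversion.
    """
    names = [s.attribute for s in schema]
    if len(set(names)) != len(names):
        raise ValueError("duplicate attribute names in schema")
    if list(matrix.columns) != names:
        raise ValueError(
            "matrix columns do not match schema "
            f"(matrix: {list(matrix.columns)!r}, schema: {names!r})"
        )
    if matrix.isna().to_numpy().any():
        raise ValueError(
            "matrix contains missing values; impute upstream before fuzzification"
        )
    if method not in ("zscore", "histogram"):
        raise ValueError(f"unknown membership method {method!r}")

    items: list[FuzzyItem] = []
    cols: list[np.ndarray] = []
    for s in schema:
        raw = matrix[s.attribute].to_numpy()
        if s.kind == "quantitative":
            col = np.asarray(raw, dtype=float)
            if log2_transform:
                if not np.isfinite(col).all() or (col <= 0).any():
                    raise ValueError(
                        f"log2 transform requires strictly positive values in "
                        f"{s.attribute!r}"
                    )
                col = np.log2(col)
            if method == "zscore":
                low, high = zscore_membership(col, ddof=ddof)
            else:
                low, high = histogram_membership(col, n_bins=n_bins)
            items.append(FuzzyItem(s.attribute, "Low"))
            cols.append(low)
            items.append(FuzzyItem(s.attribute, "High"))
            cols.append(high)
        elif s.kind == "binary":
            col = np.asarray(raw, dtype=float)
            if not np.isin(col, (0.0, 1.0)).all():
                raise ValueError(
                    f"binary attribute {s.attribute!r} contains values other than 0/1"
                )
            items.append(FuzzyItem(s.attribute, None))
            cols.append(col)
        else:  # categorical
            vals = np.asarray(raw, dtype=object).astype(str)
            unknown = set(vals) - set(s.levels)
            if unknown:
                raise ValueError(
                    f"categorical attribute {s.attribute!r} has undeclared "
                    f"levels {sorted(unknown)!r}"
                )
            for level in s.levels:
                items.append(FuzzyItem(s.attribute, level))
                cols.append((vals == level).astype(float))

    values = np.column_stack(cols) if cols else np.empty((len(matrix), 0))
    return MembershipTable(
        tuple(str(i) for i in matrix.index), tuple(items), values
    )
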