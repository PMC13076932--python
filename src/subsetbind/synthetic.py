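"""Synthetic paired matrices with planted subgroup co-occurrence structure.

The generator emulates the situation the miner is built for: a latent
patient subgroup that simultaneously elevates a small set of columns in
*both* matrices of a pair — high expression of a few biomolecules
co-occurring with a few positive clinical findings — embedded in a
noisy background of unrelated columns.

Planting follows the constant-bicluster benchmark construction:
quantitative pattern cells of subgroup members are set to ``delta``
background standard deviations plus a small coherence noise
(``pattern_noise_sd``), so the planted submatrix is internally
coherent the way a co-regulated protein module is; binary pattern
cells of subgroup members are hit with probability ``hit_probability``.
Background cells are independent standard normal / Bernoulli noise.

Ground truth records, per planted pattern, the high-side item ids the
miner should recover (``col__High`` for quantitative columns, the bare
column name for binary ones), enabling precision/recall scoring of an
emitted rule list with no external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .binding import BindingRule
from .fuzzify import ColumnSchema

__all__ = [
    "SubgroupPattern",
    "PlantedPatternSpec",
    "GroundTruthRule",
    "GroundTruth",
    "RecoveryResult",
    "generate_paired_data",
    "evaluate_recovery",
]

ColumnKind = Literal["quantitative", "binary"]


@dataclass(frozen=True)
class SubgroupPattern:
    """One planted subgroup and the columns it elevates.

    ``fraction`` is the subgroup's share of observations; ``delta`` the
    elevation of its quantitative pattern cells in background-sd units
    (0 disables planting for the whole pattern); ``hit_probability``
    the in-subgroup hit rate of its binary pattern columns;
    ``pattern_noise_sd`` the coherence noise of the planted submatrix.
    """

    fraction: float = 0.3
    kinds1: tuple[ColumnKind, ...] = ("quantitative",) * 4
    kinds2: tuple[ColumnKind, ...] = ("binary",) * 3
    delta: float = 3.0
    hit_probability: float = 0.9
    pattern_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("subgroup fraction must lie in (0, 1)")
        if not self.kinds1 or not self.kinds2:
            raise ValueError("each dataset needs >= 1 pattern column")
        if not 0.0 <= self.hit_probability <= 1.0:
            raise ValueError("hit_probability must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedPatternSpec:
    """Full description of one synthetic paired-matrix benchmark."""

    m: int = 200
    patterns: tuple[SubgroupPattern, ...] = (SubgroupPattern(),)
    n_noise_quant1: int = 50
    n_noise_binary1: int = 0
    n_noise_quant2: int = 0
    n_noise_binary2: int = 50
    background_rate: float = 0.05  # Bernoulli rate of binary background/off cells
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least 2 observations")
        for p in self.patterns:
            if math.ceil(p.fraction * self.m) < 1:
                raise ValueError("infeasible pattern: subgroup would be empty")
        if not self.allow_overlap:
            total = sum(math.ceil(p.fraction * self.m) for p in self.patterns)
            if total > self.m:
                raise ValueError(
                    "disjoint subgroups exceed the number of observations; "
                    "set allow_overlap=True or shrink fractions"
                )


@dataclass(frozen=True)
class GroundTruthRule:
    """High-side items of one planted pattern, per dataset, plus the
    planted subgroup's observation indices."""

    items1: tuple[str, ...]
    items2: tuple[str, ...]
    subgroup: tuple[int, ...]

    @property
    def items(self) -> tuple[str, ...]:
        return self.items1 + self.items2


@dataclass(frozen=True)
class GroundTruth:
    rules: tuple[GroundTruthRule, ...]
    pattern_columns1: tuple[str, ...] = ()
    pattern_columns2: tuple[str, ...] = ()


@dataclass(frozen=True)
class RecoveryResult:
    """Item-level recovery of planted patterns by an emitted rule list.

    A truth rule is recovered iff some single emitted rule contains all
    of its high-side items (on either side combined).  ``recall`` is
    the recovered fraction of truth rules (1 when there is nothing to
    recover); ``precision`` the fraction of emitted rules whose items
    all belong to a single truth rule's item set (1 when no rules were
    emitted — no false claims by convention).
    """

    precision: float
    recall: float
    recovered: tuple[bool, ...] = field(default=())


def _high_side_item(name: str, kind: ColumnKind) -> str:
    return f"{name}__High" if kind == "quantitative" else name


def _make_columns(
    rng: np.random.Generator,
    m: int,
    names: Sequence[str],
    kinds: Sequence[ColumnKind],
    background_rate: float,
) -> tuple[pd.DataFrame, list[ColumnSchema]]:
    data: dict[str, np.ndarray] = {}
    schema: list[ColumnSchema] = []
    for name, kind in zip(names, kinds):
        if kind == "quantitative":
            data[name] = rng.standard_normal(m)
        else:
            data[name] = (rng.random(m) < background_rate).astype(float)
        schema.append(ColumnSchema(attribute=name, kind=kind))
    obs = [f"obs{i:04d}" for i in range(m)]
    return pd.DataFrame(data, index=obs), schema


def generate_paired_data(
    spec: PlantedPatternSpec,
) -> tuple[pd.DataFrame, list[ColumnSchema], pd.DataFrame, list[ColumnSchema], GroundTruth]:
    """Generate the paired matrices, their schemas and the ground truth.

    Fully reproducible from ``spec.seed``.  Pattern columns are named
    ``d<1|2>sig<p>_<j>`` (p = pattern index) and noise columns ``d<1|2>noise<j>``;
    subgroups are sampled without replacement, disjoint across patterns
    unless ``allow_overlap`` is set.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.m

    names1: list[str] = []
    kinds1: list[ColumnKind] = []
    names2: list[str] = []
    kinds2: list[ColumnKind] = []
    for p_idx, pat in enumerate(spec.patterns):
        names1 += [f"d1sig{p_idx}_{j}" for j in range(len(pat.kinds1))]
        kinds1 += list(pat.kinds1)
        names2 += [f"d2sig{p_idx}_{j}" for j in range(len(pat.kinds2))]
        kinds2 += list(pat.kinds2)
    names1 += [f"d1noise{j}" for j in range(spec.n_noise_quant1)]
    kinds1 += ["quantitative"] * spec.n_noise_quant1
    names1 += [f"d1noisebin{j}" for j in range(spec.n_noise_binary1)]
    kinds1 += ["binary"] * spec.n_noise_binary1
    names2 += [f"d2noise{j}" for j in range(spec.n_noise_quant2)]
    kinds2 += ["quantitative"] * spec.n_noise_quant2
    names2 += [f"d2noisebin{j}" for j in range(spec.n_noise_binary2)]
    kinds2 += ["binary"] * spec.n_noise_binary2

    df1, schema1 = _make_columns(rng, m, names1, kinds1, spec.background_rate)
    df2, schema2 = _make_columns(rng, m, names2, kinds2, spec.background_rate)

    pool = np.arange(m)
    rules: list[GroundTruthRule] = []
    pat_cols1: list[str] = []
    pat_cols2: list[str] = []
    for p_idx, pat in enumerate(spec.patterns):
        size = math.ceil(pat.fraction * m)
        source = np.arange(m) if spec.allow_overlap else pool
        sub = np.sort(rng.choice(source, size=size, replace=False))
        if not spec.allow_overlap:
            pool = np.setdiff1d(pool, sub)

        cols1 = [f"d1sig{p_idx}_{j}" for j in range(len(pat.kinds1))]
        cols2 = [f"d2sig{p_idx}_{j}" for j in range(len(pat.kinds2))]
        pat_cols1 += cols1
        pat_cols2 += cols2
        if pat.delta == 0.0:
            continue  # null pattern: columns stay pure background
        for df, cols, kinds in ((df1, cols1, pat.kinds1), (df2, cols2, pat.kinds2)):
            for col, kind in zip(cols, kinds):
                if kind == "quantitative":
                    df.loc[df.index[sub], col] = (
                        pat.delta + pat.pattern_noise_sd * rng.standard_normal(size)
                    )
                else:
                    df.loc[df.index[sub], col] = (
                        rng.random(size) < pat.hit_probability
                    ).astype(float)
        rules.append(
            GroundTruthRule(
                items1=tuple(_high_side_item(c, k) for c, k in zip(cols1, pat.kinds1)),
                items2=tuple(_high_side_item(c, k) for c, k in zip(cols2, pat.kinds2)),
                subgroup=tuple(int(i) for i in sub),
            )
        )

    truth = GroundTruth(tuple(rules), tuple(pat_cols1), tuple(pat_cols2))
    return df1, schema1, df2, schema2, truth


def evaluate_recovery(
    rules: Sequence[BindingRule], truth: GroundTruth
) -> RecoveryResult:
    """Score an emitted rule list against the planted ground truth by
    exhaustive matching (see :class:`RecoveryResult` for conventions)."""
    truth_sets = [set(t.items) for t in truth.rules]
    recovered = tuple(
        any(ts <= set(r.items) for r in rules) for ts in truth_sets
    )
    recall = (sum(recovered) / len(recovered)) if recovered else 1.0
    if rules:
        good = sum(1 for r in rules if any(set(r.items) <= ts for ts in truth_sets))
        precision = good / len(rules)
    else:
        precision = 1.0
    return RecoveryResult(precision=precision, recall=recall, recovered=recovered)
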