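"""Readers, writers, run configuration and the three-pairing pipeline.

All artifacts are plain text: matrices and rule tables as TSV/CSV,
schemas/configs/targets as YAML (JSON is valid YAML and accepted
everywhere), itemsets and rules additionally as JSON-lines.  Outputs
are deterministically sorted and serialized so that a rerun with the
same config and inputs is byte-identical.  Conviction of a perfect
implication is serialized as the string ``"inf"`` for lossless
round-tripping through JSON and TSV.
"""

from __future__ import annotations

import json
import logging
import math
import time
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .binding import BindingConfig, BindingRule, bind
from .fuzzify import ColumnSchema, MembershipTable, fuzzify_matrix
from .mining import FuzzyItemset, MiningConfig, mine_frequent_itemsets
from .stratify import TargetItemList, select_linked_features

__all__ = [
    "read_matrix",
    "read_schema",
    "write_schema",
    "write_membership_table",
    "read_membership_table",
    "write_itemsets_jsonl",
    "read_itemsets_jsonl",
    "write_rules_tsv",
    "write_rules_jsonl",
    "read_rules_jsonl",
    "read_targets",
    "write_linked_report",
    "DatasetConfig",
    "PipelineBindingConfig",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("subsetbind")

RULE_COLUMNS = [
    "direction",
    "antecedent_items",
    "consequent_items",
    "support_antecedent",
    "support_consequent",
    "support_joint",
    "confidence",
    "lift",
    "conviction",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a delimited matrix; first column holds observation ids."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate observation ids")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index_label="observation_id")


def read_schema(path: str | Path) -> list[ColumnSchema]:
    """Read a sidecar column schema (YAML or JSON list of
    {attribute, kind, levels})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: schema file must contain a list of columns")
    return [ColumnSchema(**entry) for entry in raw]


def write_schema(schema: Sequence[ColumnSchema], path: str | Path) -> None:
    entries = []
    for s in schema:
        entry: dict = {"attribute": s.attribute, "kind": s.kind}
        if s.levels:
            entry["levels"] = list(s.levels)
        entries.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def write_membership_table(table: MembershipTable, path: str | Path) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_sep_for(path), index_label="observation_id",
                            float_format="%.12g")


def read_membership_table(path: str | Path) -> MembershipTable:
    return MembershipTable.from_frame(read_matrix(path))


def write_itemsets_jsonl(itemsets: Sequence[FuzzyItemset], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in itemsets:
            fh.write(json.dumps(
                {"items": list(f.items), "support": f.support, "size": f.size}
            ) + "\n")


def read_itemsets_jsonl(path: str | Path) -> list[FuzzyItemset]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                out.append(FuzzyItemset(tuple(d["items"]), d["support"]))
    return out


def _conviction_str(v: float) -> str:
    return "inf" if math.isinf(v) else f"{v:.12g}"


def _rule_record(r: BindingRule) -> dict:
    return {
        "direction": r.direction,
        "antecedent_items": list(r.antecedent),
        "consequent_items": list(r.consequent),
        "support_antecedent": r.support_antecedent,
        "support_consequent": r.support_consequent,
        "support_joint": r.support_joint,
        "confidence": r.confidence,
        "lift": r.lift,
        "conviction": _conviction_str(r.conviction),
    }


def write_rules_tsv(rules: Sequence[BindingRule], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RULE_COLUMNS) + "\n")
        for r in rules:
            fh.write("\t".join([
                r.direction,
                ",".join(r.antecedent),
                ",".join(r.consequent),
                f"{r.support_antecedent:.12g}",
                f"{r.support_consequent:.12g}",
                f"{r.support_joint:.12g}",
                f"{r.confidence:.12g}",
                f"{r.lift:.12g}",
                _conviction_str(r.conviction),
            ]) + "\n")


def write_rules_jsonl(rules: Sequence[BindingRule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rules:
            fh.write(json.dumps(_rule_record(r)) + "\n")


def read_rules_jsonl(path: str | Path) -> list[BindingRule]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            conv = d["conviction"]
            out.append(BindingRule(
                direction=d["direction"],
                antecedent=tuple(d["antecedent_items"]),
                consequent=tuple(d["consequent_items"]),
                support_antecedent=d["support_antecedent"],
                support_consequent=d["support_consequent"],
                support_joint=d["support_joint"],
                confidence=d["confidence"],
                lift=d["lift"],
                conviction=math.inf if conv == "inf" else float(conv),
            ))
    return out


def read_targets(path: str | Path) -> list[TargetItemList]:
    """Read target items (YAML/JSON list of {category, items:[{attribute,
    side}]})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: targets file must contain a list of categories")
    return [TargetItemList(**entry) for entry in raw]


def write_linked_report(reports, categories: Sequence[str], path: str | Path) -> None:
    """Write the linked-feature report as TSV: one row per feature, one
    check-mark column per clinical category, the category count and the
    core flag."""
    with open(path, "w") as fh:
        fh.write("\t".join(["feature", *categories, "category_count", "core"]) + "\n")
        for r in reports:
            marks = ["x" if c in r.linked_categories else "" for c in categories]
            fh.write("\t".join([r.feature, *marks, str(r.category_count),
                                "yes" if r.core else "no"]) + "\n")


# ---------------------------------------------------------------------------
# Run configuration and pipeline


class DatasetConfig(BaseModel):
    """One input dataset of a run: where it lives and how it is
    fuzzified and mined."""

    name: str
    path: str
    schema_path: str
    method: Literal["zscore", "histogram"] = "zscore"
    n_bins: int = 5
    log2_transform: bool = False
    min_support: float
    min_items: int = 1
    max_items: int | None = None

    def mining_config(self) -> MiningConfig:
        return MiningConfig(min_support=self.min_support,
                            min_items=self.min_items, max_items=self.max_items)


class PipelineBindingConfig(BaseModel):
    """Rule thresholds plus which side of each pairing supplies the
    antecedent (the omics dataset is the consequent by default)."""

    min_lift: float | None = 2.0
    min_confidence: float | None = None
    min_conviction: float | None = None
    direction: Literal["clinical->omics", "omics->clinical", "both"] = "clinical->omics"


class RunConfig(BaseModel):
    """Full configuration of a three-pairing (or n-pairing) run."""

    omics: DatasetConfig
    clinical: tuple[DatasetConfig, ...] = Field(min_length=1)
    binding: PipelineBindingConfig = PipelineBindingConfig()
    targets_path: str | None = None
    output_dir: str = "sb_out"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _unique_names(self) -> "RunConfig":
        names = [self.omics.name] + [c.name for c in self.clinical]
        if len(set(names)) != len(names):
            raise ValueError("dataset names must be unique")
        return self

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return RunConfig(**raw)


def _load_dataset(cfg: DatasetConfig) -> tuple[pd.DataFrame, list[ColumnSchema]]:
    return read_matrix(cfg.path), read_schema(cfg.schema_path)


def _align(omics: pd.DataFrame, clinical: pd.DataFrame, name: str) -> pd.DataFrame:
    """Align a clinical matrix to the omics observation order by id join."""
    if list(clinical.index) == list(omics.index):
        return clinical
    if set(clinical.index) != set(omics.index):
        missing = set(omics.index) ^ set(clinical.index)
        raise ValueError(
            f"dataset {name!r} does not cover the same observations as the omics "
            f"matrix ({len(missing)} ids differ); paired mining requires that "
            "t1,a and t2,a describe the same case"
        )
    return clinical.loc[omics.index]


def run_pipeline(config: RunConfig) -> Path:
    """Run the full workflow: fuzzify, mine and bind the omics dataset
    against each clinical dataset, then combine the per-category rule
    sets into a linked-feature report.

    Writes, under ``config.output_dir``: per-dataset itemset files,
    per-category rule files (TSV + JSON-lines), the optional linked
    -feature report and a deterministic ``manifest.json`` echoing the
    configuration and artifact row counts.  Returns the output dir.
    """
    t0 = time.perf_counter()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    omics_df, omics_schema = _load_dataset(config.omics)
    omics_table = fuzzify_matrix(
        omics_df, omics_schema, config.omics.method, n_bins=config.omics.n_bins,
        log2_transform=config.omics.log2_transform,
    )
    log.info("fuzzified omics %r: %d obs x %d items", config.omics.name,
             omics_table.n_observations, len(omics_table.items))
    omics_fis = mine_frequent_itemsets(omics_table, config.omics.mining_config())
    write_itemsets_jsonl(omics_fis, out / f"itemsets_{config.omics.name}.jsonl")
    log.info("mined %d frequent itemsets in %r", len(omics_fis), config.omics.name)

    if config.binding.direction == "clinical->omics":
        direction: Literal["1->2", "2->1", "both"] = "1->2"
    elif config.binding.direction == "omics->clinical":
        direction = "2->1"
    else:
        direction = "both"
    bind_cfg = BindingConfig(
        min_lift=config.binding.min_lift,
        min_confidence=config.binding.min_confidence,
        min_conviction=config.binding.min_conviction,
        direction=direction,
    )

    rule_sets: dict[str, list[BindingRule]] = {}
    counts: dict[str, dict[str, int]] = {
        config.omics.name: {"items": len(omics_table.items), "itemsets": len(omics_fis)}
    }
    for clin_cfg in config.clinical:
        clin_df, clin_schema = _load_dataset(clin_cfg)
        clin_df = _align(omics_df, clin_df, clin_cfg.name)
        clin_table = fuzzify_matrix(
            clin_df, clin_schema, clin_cfg.method, n_bins=clin_cfg.n_bins,
            log2_transform=clin_cfg.log2_transform,
        )
        clin_fis = mine_frequent_itemsets(clin_table, clin_cfg.mining_config())
        write_itemsets_jsonl(clin_fis, out / f"itemsets_{clin_cfg.name}.jsonl")
        # dataset 1 = clinical, dataset 2 = omics in each pairing
        rules = bind(clin_fis, omics_fis, clin_table, omics_table, bind_cfg)
        if not rules:
            log.warning("pairing %r produced no rules", clin_cfg.name)
        rule_sets[clin_cfg.name] = rules
        write_rules_tsv(rules, out / f"rules_{clin_cfg.name}.tsv")
        write_rules_jsonl(rules, out / f"rules_{clin_cfg.name}.jsonl")
        counts[clin_cfg.name] = {
            "items": len(clin_table.items),
            "itemsets": len(clin_fis),
            "rules": len(rules),
        }
        log.info("pairing %r: %d itemsets, %d rules", clin_cfg.name,
                 len(clin_fis), len(rules))

    if config.targets_path is not None:
        targets = read_targets(config.targets_path)
        # features live on the omics side = dataset 2 of each pairing
        reports = select_linked_features(rule_sets, targets, feature_side="2")
        write_linked_report(reports, [c.name for c in config.clinical],
                            out / "linked_features.tsv")
        counts["linked_features"] = {"features": len(reports),
                                     "core": sum(r.core for r in reports)}
        log.info("linked-feature report: %d features, %d core",
                 len(reports), sum(r.core for r in reports))

    manifest = {
        "tool": "subsetbind",
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return out
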