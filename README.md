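# subsetbind

Unsupervised discovery of cross-dataset co-occurrence patterns in paired
clinical–omics matrices, by fuzzy association-rule mining ("subset
binding"). Given two matrices over the same ordered observations — e.g.
an electronic-medical-record matrix (mixed binary findings, categorical
codes, continuous lab values) and a serum-proteome matrix — it finds
interpretable rules of the form

> *patients with CT findings {honeycombing, traction bronchiectasis}
> tend to have High expression of proteins {A, B, C, D}*

where the antecedent items come from one matrix and the consequent
items from the other. The intended users are computational biologists
integrating EMR-linked omics cohorts who want patient-stratification
hypotheses rather than black-box embeddings.

## Method

1. **Fuzzify.** Each quantitative attribute is converted into two fuzzy
   categorical items, `attr__Low` and `attr__High`, with a membership
   function. The z-score conversion standardises the column, divides
   by 2 and clamps to [−1, 1]; the positive part is the High
   membership, the negated negative part the Low membership (so
   Low·High = 0 and Low + High ≤ 1). A histogram-based conversion with
   ramps anchored at the modal bin centre is also provided. Binary
   columns pass through as crisp items; categoricals are one-hot
   expanded.

2. **Mine.** Frequent fuzzy itemsets are detected independently in
   each matrix with a levelwise (Apriori) search under a per-dataset
   minimum support, where the fuzzy support of an itemset X over m
   observations is

   ```
   support(X) = (1/m) Σ_a min_{i∈X} μ_i(a)
   ```

   The min t-norm makes support anti-monotone, which prunes the search.

3. **Bind.** Rules X → Y pair a frequent itemset from one dataset with
   one from the other and are scored with

   ```
   support(X→Y)    = (1/m) Σ_a min(X(a), Y(a))
   confidence(X→Y) = support(X→Y) / support(X)
   lift(X→Y)       = support(X→Y) / (support(X)·support(Y))
   conviction(X→Y) = (1 − support(Y)) / (1 − confidence(X→Y))
   ```

   and pruned by a minimum lift (optionally confidence/conviction).
   Lift is 1 under independence; values above 1 indicate
   stronger-than-chance co-occurrence.

4. **Stratify.** Rule sets from several clinical categories (medical
   records, CT reports, blood tests, …) are combined: features that
   appear in rules containing user-designated disease-characteristic
   target items are collected per category, and features linked to two
   or more categories are flagged as *core* features.

A seeded synthetic-data generator plants a latent patient subgroup
that simultaneously elevates a few columns of both matrices (a
coherent bicluster) inside an independent noisy background, with
ground truth for recovery scoring — so the whole pipeline is testable
end-to-end without any cohort data.

## Worked example

```python
from subsetbind import (
    BindingConfig, MiningConfig, PlantedPatternSpec, bind,
    evaluate_recovery, fuzzify_matrix, generate_paired_data,
    mine_frequent_itemsets,
)

# paired matrices with a planted subgroup (30% of 200 cases) that raises
# four omics columns and three binary clinical findings together
omics_df, omics_schema, clin_df, clin_schema, truth = generate_paired_data(
    PlantedPatternSpec(seed=1))

omics = fuzzify_matrix(omics_df, omics_schema)        # 54 cols -> 108 items
clinical = fuzzify_matrix(clin_df, clin_schema)       # 53 binary items

fis_omics = mine_frequent_itemsets(omics, MiningConfig(min_support=0.15, min_items=4))
fis_clin = mine_frequent_itemsets(clinical, MiningConfig(min_support=0.02, min_items=3))
rules = bind(fis_clin, fis_omics, clinical, omics, BindingConfig(min_lift=2.0))
```

This prints (`print` statements elided):

```
omics itemsets: [(('d1sig0_0__High', 'd1sig0_1__High', 'd1sig0_2__High', 'd1sig0_3__High'), 0.175)]
clinical itemsets: 45  rules: 45
top rule: ('d2noisebin35', 'd2sig0_0', 'd2sig0_1') -> ('d1sig0_0__High', 'd1sig0_1__High', 'd1sig0_2__High', 'd1sig0_3__High')
  lift=3.47 confidence=0.61 support=0.015
recovery: RecoveryResult(precision=0.022..., recall=1.0, recovered=(True,))
```

The only frequent 4-item omics set is exactly the planted High
signature (support 0.175 ≥ the 0.15 floor), every emitted rule has the
planted omics signature as its consequent, and one of them contains
all seven planted items — recall 1. The lift of the planted rule is
close to 1/0.3 ≈ 3.3, the closed-form lift of a pattern fully nested
in a 30% subgroup. Precision at the rule level is low here by design:
with a 0.02 clinical support floor, many clinical itemsets mixing
planted and background findings also clear the lift threshold.

### Command line

The same flow is scriptable: `sb simulate`, `sb fuzzify`, `sb mine`,
`sb bind`, `sb select`, and `sb run --config run.yaml` for the full
multi-pairing pipeline (one omics dataset bound against each clinical
category, then core-feature selection). All artifacts are TSV /
JSON-lines / YAML; reruns with the same config are byte-identical.

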