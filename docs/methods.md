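# Methods

## Problem setting

Two matrices T₁ and T₂ describe the same m observations (cases) in the
same order — typically a clinical matrix (binary findings, categorical
codes, continuous lab values) paired with an omics matrix (continuous
protein abundances). The goal is to find itemsets that are frequent
within each matrix and co-occur across the pair more often than chance,
expressed as association rules whose antecedent items come from one
matrix and consequent items from the other. Mining happens at the
*case* level: repeated measurements of one patient are treated as
independent observations, which overstates the effective sample size
when within-patient correlation is strong; callers who care should
collapse to one row per patient upstream.

## Fuzzification

Quantitative attributes become two fuzzy items, `attr__Low` and
`attr__High`.

**Z-score conversion** (default): per column, z = (x − mean)/sd, then
v = clamp(z/2, −1, 1), High = max(v, 0), Low = max(−v, 0). The split
into opposing sides is forced by two requirements: memberships must
lie in [0, 1], and Low and High of one attribute must never be
simultaneously positive (Low·High = 0, Low + High ≤ 1). The standard
deviation uses the population formula (ddof = 0) for determinism;
`ddof` is configurable. Division by 2 means an observation needs
|z| ≥ 2 for full membership — memberships saturate at two standard
deviations.

**Histogram conversion**: an equal-width histogram with `n_bins`
(default 5) locates the modal bin (ties break to the lowest index, for
determinism); with modal centre c, Low(x) = clamp((c − x)/(c − min),
0, 1) and High(x) = clamp((x − c)/(max − c), 0, 1). The linear ramps
anchored at the mode are one natural reading of a histogram-anchored
membership function; the exact functional form is a design choice
here, kept behind `HistogramMembershipParams` so an alternative
parameterisation can be supplied explicitly.

Degenerate inputs: a constant column has no Low/High gradation and
yields all-zero memberships with a warning; missing values are a hard
error — imputation is an upstream, domain-specific decision, not part
of the miner. Binary columns must be exactly {0, 1}; categorical
columns are one-hot expanded over their declared levels. Attribute
names may not contain `__`, the item-name separator.

## Mining

Fuzzy support of an itemset S: (1/m) Σ_a min_{i∈S} μ_i(a). The min
t-norm is used *within* an itemset for internal consistency with the
rule-level joint support (below): an itemset's support then
specialises the rule formula when the itemset is split across a rule.
Min is anti-monotone, so the classical levelwise Apriori search
applies: candidates of size k+1 are generated by joining frequent
k-itemsets sharing a (k−1)-prefix in lexicographic order, pruned if
any k-subset is infrequent or if the candidate would combine Low and
High of one attribute (their joint membership is identically zero
under z-score conversion, and the itemset would be uninterpretable).

`min_items`/`max_items` are eligibility filters on *reported* itemsets
(and therefore on rule sides); growth always starts from singletons
because Apriori needs the full lattice below any reported set.
`max_items` defaults to unbounded — termination is natural when no
candidate survives `min_support` — with the option serving as a safety
cap for adversarial inputs. Output order is (size, support
descending, lexicographic items), making serialized output
byte-stable.

## Binding and rule metrics

For a rule X → Y with X(a) = min membership over X's items:

- support(X→Y) = (1/m) Σ_a min(X(a), Y(a))
- confidence = support(X→Y)/support(X)
- lift = support(X→Y)/(support(X)·support(Y))
- conviction = (1 − support(Y))/(1 − confidence)

Conviction at confidence 1 is +∞ when support(Y) < 1 (perfect
implication of a non-trivial consequent) and defined as 1 when the
consequent is universal; it is serialized as the string `"inf"` for a
lossless text round-trip. Pruning is by `min_lift` (the published
configuration uses 2) plus optional confidence/conviction floors; no
joint-support threshold is applied at the rule stage — the per-dataset
support and size filters are what keep the cross product tractable.
Rules are sorted by (lift desc, joint support desc, antecedent,
consequent). The default pipeline direction makes the clinical
dataset the antecedent and the omics dataset the consequent;
"both" additionally emits the mirror rules (same support and lift,
direction-specific confidence/conviction).

## Core-feature selection

Given per-category rule sets and per-category target items (attribute
plus membership side, `any` as a wildcard), a feature is *linked* to a
category iff it appears on the feature side of at least one of that
category's rules whose clinical side contains at least one target
item. Features linked to ≥ 2 categories are *core*. Target matching
is by the designated item, not by any item of the category — the
stricter reading; the wildcard side exists because targets are often
named as attributes without a direction.

## Synthetic benchmark

The generator emulates the intended discovery scenario: a latent
subgroup of ⌈ρm⌉ observations (default ρ = 0.3, m = 200) that
simultaneously elevates k₁ quantitative columns in dataset 1 (default
4) and k₂ binary columns in dataset 2 (default 3), inside a background
of independent standard-normal columns (50 per dataset by default) and
sparse Bernoulli(0.05) indicator columns matching the one-hot sparsity
of structured radiology findings.

Planting follows the coherent (constant) bicluster construction used
by bi-clustering benchmarks: planted quantitative cells are set to
δ·sd (default δ = 3, in background-sd units) plus within-block noise
of sd 0.25, and planted binary cells are Bernoulli(0.9). Coherence
matters, not just effect size: because z-score memberships saturate at
|z| = 2 and a 30% subgroup caps its own z-scores near 1.5, the High
membership of subgroup members tops out around 0.6–0.75, and the min
over k₁ *independently* noisy columns would push the 4-item support to
≈ 0.10 — below a 0.15 support floor no matter how large δ is. A
coherent block (as a co-regulated module is) keeps the 4-item support
at ≈ 0.17. This is a real sensitivity of the method worth knowing
about: it detects subgroups whose pattern columns move *together*, and
fades as within-subgroup dispersion across pattern columns approaches
the background dispersion.

Subgroups are sampled without replacement and disjoint across multiple
patterns unless overlap is requested; δ = 0 disables planting entirely
and marks the ground truth empty. What the generator does **not**
emulate: mass-spectrometry missingness (inputs here are complete by
contract), EMR coding noise and redundancy, correlated background
(batch effects), or heavy-tailed abundance distributions. Passing the
recovery benchmark therefore shows the machinery is correct and the
thresholds coherent — not that real-cohort performance is guaranteed.

Recovery scoring: a planted rule counts as recovered iff a single
emitted rule contains all its high-side items; recall is the recovered
fraction of planted rules (1 when nothing was planted), precision the
fraction of emitted rules whose items all belong to one planted rule's
item set (1 when no rules were emitted — no false claims).

## Numerical and interface choices

- All sorting keys are total orders → byte-identical reruns; the run
  manifest contains only deterministic content (wall time goes to the
  log stream, not the manifest).
- Supports are plain float64 means; the oracle-equivalence tests check
  agreement with exhaustive enumeration to 1e−12.
- Observation pairing in the pipeline is by explicit ID join (rows
  reordered to the omics order); a mismatch in ID *sets* is an error,
  because rule supports are meaningless across mispaired rows.
- The benchmark sizes used by the test suite and the acceptance script
  (m = 200, ≈ 55 columns per dataset, 20 + 20 replicates, 100+ oracle
  tables with ≤ 12 observations and ≤ 8 items) keep a full run in the
  tens of seconds while leaving the support estimates' standard errors
  (≈ 0.005) an order of magnitude below the decision margins.

## Known limitations

- The cross product of two large frequent-itemset collections is
  evaluated exhaustively; extreme threshold choices (e.g. very low
  min support with min_items = 1 on dense data) can explode. The
  per-dataset support/size filters are the intended mitigation.
- No statistical significance testing of rules is performed; lift
  thresholds plus support-based pruning are the only overfitting
  controls.
- The z-score conversion's membership ceiling for large subgroups
  (see above) biases the method toward minority subgroups; for
  subgroup fractions approaching 0.5 the histogram conversion or a
  lower support floor is more appropriate.
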