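# Methods

This document defines the models implemented in `cfmhl`, the conventions
they follow, the parameters and their defaults, and the generative model
behind the synthetic cohorts. Nothing here makes empirical claims beyond
what the test suite and `scripts/acceptance.py` compute.

## 1. Haplotype metrics

A *haplotype record* is a contiguous pattern over `{M, U}` observed on one
or more sequenced molecules of a methylation haplotype block (MHB), with a
read count and a CpG offset within the block.

**uMHL.** For window length `i`, `P(UMH_i)` is the count-weighted fraction
of all contiguous length-`i` windows of the observed patterns that consist
entirely of `U`. The unmethylated haplotype load is

```
uMHL = Σ_i w_i · P(UMH_i) / Σ_i w_i ,   w_i = i^k
```

with `weight_exponent k = 3` by default. Window lengths at which no window
is observed (all patterns shorter than `i`) are excluded from both the
numerator and the denominator, so shallow coverage is not penalised for
unobservable lengths. **MHL** is the identical computation over fully-`M`
windows; **AMF** is the count-weighted fraction of `M` calls. All three
lie in `[0, 1]`; a block with no records is missing (NaN).

The cubic default deliberately emphasises long single-molecule runs of
unmethylated CpGs, the signature of coordinated demethylation in DNA
released by dying tissue. `weight_exponent = 0` recovers an unweighted
average over lengths; negative exponents are rejected.

**Matrix assembly** (`build_matrix`): cell (sample, block) carries the
metric only when that sample's total read count for the block reaches
`min_reads = 3`; otherwise it is missing. A block id not present in the
panel is a validation error. `filter_blocks` keeps blocks non-missing in
at least `min_sample_fraction = 0.8` of samples; coverage exactly at the
threshold is kept.

## 2. Marker screens

Both screens operate on the uMHL matrix and return an immutable
`MarkerSet` recording the parameters used.

**Sample-level AP screen** (`screen_ap_markers`): a block is selected iff

- strictly more than 50% of healthy samples have uMHL < 0.1, **and**
- strictly more than 40% of severe-AP samples have uMHL ≥ 0.1.

Missing cells are excluded from both the numerator and the denominator of
each fraction. All comparisons on the fractions are strict (`>`), and the
value comparisons at 0.1 are `<` / `≥` exactly as written, so boundary
behaviour is fully specified.

**Case-level severity screen** (`screen_sap_markers`): serial samples of
one patient form a *case*. For a given block, a MAP case passes iff its
per-case maximum uMHL < 0.7 and mean < 0.5; a SAP case passes iff its
minimum > 0.3 and mean > 0.5. Cases with no non-missing value for the
block are not evaluable and are dropped from the denominator. A block is
selected iff strictly more than 65% of evaluable MAP cases pass **and**
strictly more than 65% of evaluable SAP cases pass. Using extremes as
well as means demands that the separation hold across a patient's whole
sampled time course, not just on average.

**Aggregate score** (`aggregate_score`): the arithmetic mean of a sample's
non-missing uMHL values over the marker set; missing when fewer than
`min_covered_fraction = 0.5` of the markers are covered. The unweighted
mean is a deliberate modelling choice: it keeps the score interpretable as
"average marker uMHL" and makes no assumption about relative marker
importance.

**Classification** (`classify`): positive iff score ≥ cutoff; samples with
a missing score are unclassified (NA). **Cutoff selection**
(`choose_cutoff`): the Youden index J = sensitivity + specificity − 1 is
maximised over the midpoints between consecutive distinct training scores
(plus outer candidates below the minimum and above the maximum); ties are
broken toward the higher cutoff, i.e. toward higher specificity. A
degenerate input with a single distinct score warns and returns that
value.

## 3. Evaluation

- **ROC/AUC** (`roc_auc`): built on scikit-learn's `roc_curve`/`auc` with
  `drop_intermediate=False`; trapezoidal AUC. Samples with missing scores
  are excluded and counted. The AUC equals the Mann–Whitney probability
  that a random positive outscores a random negative, with ties counted
  half — the test suite verifies this equivalence against an independent
  pair-counting implementation.
- **Welch's t-test** (`welch_t`): scipy's unequal-variance t-test with
  Satterthwaite degrees of freedom, cross-checked against the closed-form
  formula in the tests. Two zero-variance groups with equal means return
  (t = 0, p = 1); with unequal means the statistic is undefined and an
  error is raised.
- **Case-level splits** (`split_cases`): patients (cases), not samples,
  are assigned to train or test, stratified by group; within each group
  the case list is sorted, permuted with a seeded generator, and the first
  `floor(n · fraction + 0.5)` cases train. All serial samples of a case
  stay on the same side — the tests verify no case ever spans the split
  across 100 seeds. A single-case group goes to training with a warning.
- **Marker intersection** (`intersect_markers`): set intersection of block
  ids, preserving the first set's order.

## 4. Clinical severity models

- **Availability filter**: drop a test missing in strictly more than 20%
  of training samples; exactly 20% is kept.
- **Preprocessing**: median imputation then z-scoring, with the medians,
  means and standard deviations estimated on training data only and
  stored in a `PreprocessRecord` that is re-applied verbatim to test
  data. A zero-variance test is given scale 1 with a warning. The tests
  verify that no test-set statistic influences the transform.
- **Logistic regression** (`fit_logistic`): maximum likelihood via
  statsmodels `Logit` (Newton, tolerance 1e-8). On non-convergence or
  coefficient blow-up (|β| > 1e3, the signature of complete separation) it
  falls back to L2-regularised estimation (scikit-learn, α = 1.0) with a
  warning. The model stores its standardization map so `predict` can be
  applied to raw feature tables.
- **Recursive feature elimination** (`rfe_select`): our own loop — refit,
  drop the feature with the smallest |coefficient|, repeat — so the full
  elimination order is returned; the tests cross-check the selected set
  against scikit-learn's `RFE`.
- **Reference 12-test model** (`table1_fixture`): a fixed logistic model
  over 12 routine blood tests (coefficients, units, and per-test ranges
  hard-coded). It has **no intercept**, so `predict` on it returns a
  *relative* severity score (a warning is emitted and an intercept of 0 is
  used): rankings and AUCs are meaningful, absolute probabilities are not.
- **Expanded model** (`build_expanded_features`): inner join of the
  clinical features with the aggregate methylation score as one more
  column (`umhl_sap_score`).

## 5. Synthetic cohort generator

The generator exists to validate the pipeline: it plants known marker
blocks and clinical effects and returns the ground truth alongside the
data. Defaults (all in `CohortConfig`):

- **Cohort**: 12 healthy, 9 MAP, 22 SAP cases; healthy cases contribute
  one day-0 sample, patient cases 2–3 serial samples at days 1/3/7.
- **Panel**: 2000 blocks of 4–8 CpGs; 100 planted AP marker blocks and 60
  planted severity marker blocks, disjoint.
- **Methylation model**: each (sample, block) draws an unmethylation
  propensity `p ~ Beta(μκ, (1−μ)κ)` with concentration `κ = 30` around a
  group-specific mean: background `μ = 0.05` everywhere; at AP markers
  `μ = 0.03` (healthy) vs `0.35` (MAP and SAP); at severity markers
  `μ = 0.25` (MAP) vs `0.75` (SAP). Read counts are negative binomial
  (mean 25, shape 3); 5% of blocks are low-coverage (mean 1.5 reads) to
  exercise the missingness path. Each read is a *coherent mixture*: with
  probability `read_correlation = 0.9` the whole molecule is `U` with
  probability `p` (else whole-`M`), otherwise CpGs are independent
  Bernoulli(`p`). High coherence is the defining property of an MHB —
  methylation states within a block are coordinated on the same molecule —
  and it is what lets per-CpG rates express as well-separated uMHL values
  under the cubic length weighting. All reads span the full block
  (offset 0); the I/O layer supports partial patterns with offsets, but
  the generator does not emit them.
- **Clinical tests**: the 12 reference tests are drawn from truncated
  normals within their recorded ranges, with an SAP mean shift of
  sign(coefficient) · (max − min)/6 · `clinical_effect_scale`; 45
  additional noise tests have no group effect. Values are missing
  completely at random with probability 0.05.
- **Determinism**: all randomness flows from a single seed; regenerating
  with the same seed reproduces every output file byte for byte. Reads
  are represented internally as bit-mask integers for speed.

**What the generator does not emulate**: fragment-length and
partial-coverage effects (all reads are full-block), batch or
sequencing-depth effects beyond the NB read-count model, within-case
temporal trends (serial samples of a case are exchangeable draws),
correlations between clinical tests, informative (non-MCAR) missingness,
and any genome-level structure (blocks are independent).

## 6. Numerical conventions

- Matrix TSVs are written with `repr`-formatted doubles and read with
  pandas' round-trip float parser, so serialisation is bit-exact.
- All fraction thresholds in the screens are strict (`>`); all value
  thresholds are as written above, with boundary cases covered by tests.
- Train-count rounding in splits is half-up (`floor(n·f + 0.5)`), not
  banker's rounding.
- Seeds are handled with `numpy.random.default_rng`; derived seeds stay
  below 2³¹.

## 7. Limitations

- The 12-test reference model lacks an intercept; it supports ranking and
  discrimination analyses only.
- The screens' cutoffs (0.1; 0.7/0.5/0.3; 50%/40%/65%) are fixed
  domain-motivated constants, not tuned per dataset; only the aggregate
  score cutoff is data-driven (Youden on training data).
- The generator's group separations are idealised; recovery rates and
  AUCs on synthetic cohorts characterise the pipeline's correctness, not
  expected performance on clinical data.
- Published marker panels from prior studies are not bundled; analyses
  intersecting external panels require the user to supply them.
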