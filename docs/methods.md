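# Methods

## Problem setting

A candidate two-drug combination is represented by the elementwise sum
of the two drugs' feature vectors within one feature category (targets,
pathways, metabolic enzymes, transporters — binary per drug — or side
effects, dose-coded 0/1/2 per drug). Effective combinations form the
positive class; non-effective pairs are sampled, either from the drugs
occurring in positive pairs (strategy N1) or from a wider catalogue
(N2), always excluding known positives and self-pairs. Pairs are stored
canonically as (lexicographic min, max) so unordered equality and the
positive-exclusion check are well defined. Pairs lacking feature data
for either drug are dropped, not imputed.

## Feature screening

Screening works on binarized pair features (any nonzero code → 1).
With `p1` the feature frequency among negatives and `p2` the frequency
over all labeled pairs, a null feature satisfies `p2 ≈ p1` with binomial
noise whose tolerated magnitude depends on `p1`: near `p1 = 0.5` the
frequency is most variable, near 0 or 1 least. That geometry is captured
by the ellipse `(p1−0.5)²/0.5² + (p2−p1)²/a² = 1` with significance
semi-axis `a`. Rather than hard-coding an `a`, we compute each feature's
*critical* semi-axis

```
a* = |p2 − p1| / sqrt(1 − (p1 − 0.5)²/0.25)
```

(`a* = 0` when `p2 = p1`; `a* = ∞` when `p1 ∈ {0,1}` and `p2 ≠ p1`) and
rank features by `a*` descending, ties broken toward the lower feature
index. Taking the top `m` (default 30) reproduces any fixed-`a`
"outside the ellipse" rule as a special case and makes `m` the single
tuning knob. A label-permutation utility (`null_calibration`) estimates
the null distribution of `a*` for users who prefer to calibrate a fixed
`a` instead. `p2` is computed on labeled pairs only; the unlabeled pool
carries no labels and enters nowhere in screening. Dose codes are
binarized for screening but kept raw for classification (both steps are
independently configurable).

The comparison selector is greedy mRMR in the MID (difference) scheme
with plug-in mutual information on the discrete codes: the first pick
maximizes MI with the label, each later pick maximizes
`MI(f; y) − mean MI(f; selected)`, ties to the lower index.

## The correlation-eigenbasis classifier

The classifier is a class-conditional Gaussian discriminant built in the
eigenbasis of the feature correlation matrix. Its premise: marginal
distributions and inter-feature correlation do not depend on class
labels, so they may be estimated from *all* available pairs — including
a large unlabeled candidate pool — while only the class-conditional
means and spreads require labels. This targets the small-`n`, large-`p`
regime where plain naïve Bayes both ignores correlation and overfits.

Fitting:

1. **Normal transform.** Each raw feature column of all samples
   (labeled ∪ unlabeled) is mapped by the rank-based inverse normal
   transform with Blom offset, `value → Φ⁻¹((r − 3/8)/(n + 1/4))`, using
   average ranks for ties. The transform is distribution-free and gives
   the sum-coded discrete features approximately standard-normal scores.
   Held-out samples are mapped by monotone interpolation of the fitted
   (value, score) knots, clipping beyond the fitted range; constant
   columns are flagged and map to 0.
2. **Eigenbasis.** `R = corr(Ẑ)` over all transformed samples, then
   `R = P diag(λ) Pᵀ` (eigenvalues sorted descending). Columns with zero
   variance keep unit diagonal and zero off-diagonals.
3. **Moments.** Class means/SDs `(μₖ, σₖ)` on the transformed labeled
   rows per class; overall means/SDs `(μ, σ)` on all transformed rows,
   consistent with their use in the overall-standardized projection.
   SDs are population SDs (ddof = 0). Priors default to empirical class
   frequencies.

Scoring a sample `x̂` (transformed):

```
β  = ((x̂ − μ)/σ) P          γₖ = ((x̂ − μₖ)/σₖ) P
Hₖ = ln P(Cₖ) − Σᵢ (γₖᵢ²/(2λᵢ) + ln σₖᵢ)
Lₖ = Σᵢ (βᵢ² − γₖᵢ²)/λᵢ
```

`argmax Hₖ` is the prediction when priors are meaningful (exact ties go
to the non-effective class — conservative for a screening tool). `Lₖ`
compares the class-standardized against the population-standardized
Mahalanobis-type distance; larger values mean the sample looks more like
class k than like the pooled population, and a threshold is chosen on a
calibration ROC (Youden's J by default, closest-to-(0,1) as an
alternative).

Modelling notes, made deliberately and documented here:

* `γₖ` reuses the *common* eigenbasis `P` of the pooled correlation
  matrix rather than per-class bases; the model assumes class-invariant
  correlation and lets only the first moments differ.
* `Hₖ` carries no `½ ln λᵢ` term. Since `λ` is shared across classes the
  omission shifts every `Hₖ` equally and never changes the argmax; we
  keep the score in its minimal form.
* Regularization floors: `λᵢ ← max(λᵢ, 10⁻⁶ n)` rescaled so `Σλᵢ = n`
  (the trace of a correlation matrix), and `σ ← max(σ, 10⁻⁶)`. The
  scores divide by `λ` and take `ln σ`; degenerate columns would
  otherwise produce infinities. The floors are deliberately tiny: a
  feature constant within a class *is* near-decisive evidence and is
  allowed to dominate, just not to become infinite.
* With `R = I` the `Hₖ` ranking reduces termwise to the independent
  Gaussian log-posterior; the test suite verifies exact decision
  agreement with an independently coded Gaussian NB in that limit, and
  the results object round-trips through JSON to 1e−12.

## Baselines

All baselines implement `fit` / `predict` / `decision_function` so the
evaluation harness treats every classifier interchangeably. Fixed
hyperparameters: RBF SVM with C = 10, γ = 0.1; KNN with k = 5 and
minimum winning vote l = 2 (an indefinite vote falls back to
non-effective; with binary labels and k = 5 the winner always has ≥ 3
votes, so the rule matters only for other settings); categorical naïve
Bayes with Laplace smoothing 0, meaning a feature value never observed
within a class vetoes that class (−∞ log-likelihood), and a sample
vetoed by every class falls back to the larger prior. KNN and SVM
delegate to scikit-learn internally; the categorical NB is implemented
directly because the zero-smoothing veto-and-fallback semantics are part
of its contract. Baselines consume the same selected, sum-coded features
as the eigenbasis model.

## Evaluation protocol

* Metrics: accuracy, recall, specificity, precision, F-measure, MCC from
  the confusion counts. A ratio whose denominator vanishes because the
  corresponding error count is zero is 1; an undefined MCC or F-measure
  is 0. Display rounding is 4 decimals, half-up (0.69565… → 0.6957).
* ROC by threshold sweep over observed scores, AUC by the trapezoidal
  rule; this equals the concordant-pair (Mann–Whitney) statistic with
  half credit for ties, and a brute-force oracle enforces the identity
  to 1e−12 in the tests.
* LOOCV refits the entire estimator — feature selection included —
  inside every fold; the alternative leaks held-out labels into the
  selector. Folds whose training part loses a class are skipped with a
  warning.
* Independent tests use a uniform random, non-stratified 75/25 split
  (train size = floor(0.75 n); 202 samples split 151/51).
* Ratio sweeps draw 1:1, 1:2, 1:3 negatives, split 75/25 and report
  independent-test metrics per ratio.
* y-randomization permutes labels (class counts preserved), rebuilds
  everything and reports LOOCV ROC for the original and each shuffle.
* `recover_confusion_from_metrics` exhaustively searches integer
  confusion matrices whose accuracy/recall/precision round to given
  4-decimal values within a test-set size range — the tool used to audit
  published metric tables for internal consistency (each audited row
  admits exactly one matrix, whose MCC and F-measure reproduce the
  printed values).

## Synthetic studies

The generator emulates the statistical shape of real per-drug feature
tables, not any specific database:

* **Drug universe.** Latent Gaussian copula with equicorrelated feature
  blocks (`block_size`, `block_correlation`), thresholded per feature to
  the target prevalence; side effects use a second threshold to split
  occurrences into low/high dose. Everything is driven by one seed.
* **Planted pair-level signal.** Each positive pair owns two dedicated
  drug rows. For each informative feature, exactly `round(e·k)` of the
  `k` positive pairs are enriched (the feature is switched on in one of
  the two drugs), with `e = effect_size / (1 − q̄)` where
  `q̄ = 1 − (1 − p̂)²` is the baseline binarized pair-level frequency
  from the universe's empirical prevalence `p̂`. This makes the
  positive-vs-negative frequency difference on planted features equal
  `effect_size` up to baseline sampling noise, hence a screening
  contrast `p2 − p1 ≈ effect_size/2` at 1:1. Informative features are
  spread round-robin across correlation blocks. The unit of signal
  injection is the pair, matching the unit of analysis.
* **Negatives and pool.** N2 draws from the universe's non-positive
  drugs (emulating a catalogue much larger than the labeled set); N1
  re-pairs the enriched positive drugs, which *attenuates* the observed
  contrast — the same phenomenon that makes N1 benchmarks harder than
  N2 benchmarks on real data. The unlabeled pool is drawn from the same
  universe, disjoint from every labeled pair.
* **Presets** expose the real per-category feature dimensionalities
  (targets 681/787, pathways 255/263, enzymes 135/146, transporters
  76/86, side effects 3005/3889 for N1/N2); defaults are smaller
  (200 features, 100 positive pairs, prevalence 0.1, latent block
  correlation 0.4, effect 0.2) so tests run in seconds.

What the generator does **not** emulate: drug sharing across positive
pairs (each positive pair has dedicated drugs), heavy-tailed marginal
prevalences, cross-category dependence, and any database-specific
identifier structure. Passing tests therefore demonstrate correctness of
the algorithms and the claimed *qualitative* orderings under the model's
own assumptions, not performance on any real benchmark.

## Study conditions used by the tests and the acceptance script

The correlated benchmark uses 40 features in eight blocks of five with
latent correlation 0.9 — chosen because thresholding and sum-encoding
shrink correlation, and this setting yields ≈ 0.6 *observed* within-
block correlation between encoded pair features — 16 informative
features spread two per block, effect 0.2, 80 positive pairs at 1:1 and
a 300-pair unlabeled pool. Screening recovery uses effect 0.3 with 400
labeled pairs over 200 features (20 planted). y-randomization uses
effect 0.3, 120 labeled pairs, three shuffles. These sizes keep a full
LOOCV replicate set under two minutes on one CPU while leaving the
qualitative effects far above Monte-Carlo noise.

## Known limitations

* Binary two-drug combinations only; no higher-order recipes.
* The shared-correlation assumption is untested on real data here; if
  classes differ in correlation structure the common eigenbasis is
  misspecified.
* The rank transform cannot make a two-point (low-prevalence binary)
  feature truly Gaussian; the discriminant then operates on a
  two-to-five-point transformed scale, which works in practice but
  weakens the normality interpretation.
* Plug-in MI in the mRMR baseline is upward-biased at small n; rankings
  among near-null features are noisy.
* No identifier mapping, database retrieval, or multiple-testing layer.
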