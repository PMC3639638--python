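# Methods

This note documents the statistical models implemented in `genestab`, the
synthetic data they are exercised on, the numerical choices made where a
definition leaves room, and what the package's tests do and do not show
about real expression data.

## Setting and notation

A study is a real matrix `X` of `n` samples by `p` genes (log-ratio
expression, already filtered upstream — the package neither normalises nor
imputes) paired with outcomes `y ∈ {-1, +1}` (-1 good prognosis, +1
metastasis) and, optionally, binary ER/PR hormone statuses. The regime of
interest is `p ≫ n`: a prognostic signature is a small gene subset plus a
fitted discriminant `F(x)` and threshold, and the package's purpose is to
measure how *non-unique* such signatures are.

## Discriminant methods

All four methods share one Model/Results contract: the model is built from
`(expression, phenotypes, gene subset)` and `fit()` returns a results
object with the fitted parameters, a decision threshold, training metrics
and `score` / `predict` / `evaluate` / `summary`.

**One-class correlation scorer.** `μ̂⁻` is the per-gene mean over the
good-prognosis training samples; a sample is scored by minus the Pearson
correlation, taken *across genes*, between its expression vector and `μ̂⁻`
(both vectors centred by their gene-wise means). Scores live in [-1, 1];
large scores mean dissimilar to the good-prognosis template. The gene-wise
centring makes the score invariant to positive affine transforms of the
sample vector.

**Diagonal LDA.** The Gaussian log-likelihood-ratio score with the
covariance restricted to its diagonal. The variance is the per-gene
variance of the pooled training sample (both classes together, ddof 1) by
default — the `pooled_within` option uses the class-centred variant for
comparison. Degenerate per-gene variances are floored at
`1e-8 × median(variance)` and logged, keeping the score finite; the prior
term is `log(n₊/n₋)`.

**AdaBoost.** The weak-learner dictionary contains every one-gene stump
with cuts at midpoints of consecutive distinct training values (constant
genes contribute none). Selection maximises `|ε - 1/2|` over the
dictionary, which is equivalent to minimising the weighted error over the
orientation-doubled stump set, since a stump and its flip differ only in
the sign of the coefficient `β = ½ log((1-ε)/ε)`. Ties break toward the
smallest gene index, then the smallest cut, so the fit is deterministic and
invariant to sample order. Weighted errors are clipped to
`[1/(2n), 1 - 1/(2n)]` before the log, keeping `β` finite with minimal
bias; clipping is logged and, on non-separable data, never triggers. The
per-round diagnostics record the weighted error, coefficient, exponential
loss and the just-chosen stump's error under the updated weights; the
latter equals 1/2 identically, which the test suite checks to 1e-10. `T`
defaults to 100 with no early stopping.

**AUCBoost.** The objective is the Gaussian-smoothed AUC — the Heaviside
in the pairwise AUC statistic replaced by `Φ((F(x⁺)-F(x⁻))/σ)` — minus
`λ` times the summed integrated squared second derivative of each gene's
score component. Rescaling `(F, σ)` jointly leaves the smoothed AUC
unchanged, so `σ` is fixed at 1 without loss of generality. Weak learners
are natural-cubic-spline basis functions of single genes, standardized to
unit training SD:

* knots: 5 per gene, at the equally spaced quantiles {1/6, …, 5/6} of the
  gene's training values (quantile knots are standard practice; genes with
  fewer distinct values than knots fall back to a linear-only learner,
  logged);
* basis: the truncated-power natural basis (constant, identity, and the
  `d_l - d_{m-1}` combinations), linear beyond the boundary knots; the
  constant function is never a learner;
* the roughness Gram matrix `∫ N_a'' N_b''` is computed in closed form by
  per-interval Simpson quadrature, which is exact because natural-spline
  second derivatives are piecewise linear between knots. The penalty is
  kept on the *cumulative* per-gene component, so re-selecting a gene
  accounts for cross-terms with its previously chosen bases.

Each round takes, for every candidate learner, a one-step Newton–Raphson
coefficient from `β = 0` on the penalised objective (analytic first and
second derivatives of the pairwise `Φ` sum and the quadratic penalty). At
`F = 0` the curvature of the smoothed-AUC term vanishes, and it can be
non-negative elsewhere; whenever the Newton step is undefined the
coefficient falls back to the best of the fixed steps {±0.1, ±0.5, ±1}
(counted and reported on the results object). The candidate with the best
penalised objective at its step is appended. `(λ, T)` are selected
jointly: stratified k-fold cross-validation (default 5 folds, λ grid
{1e-3, 1e-2, 1e-1, 1, 10}, T up to 20) tracks the validation smoothed AUC
after every round, the maximising pair wins (ties toward the earlier grid
entry and the smaller T), and the model is refitted on all training data.
The one-step coefficients make no monotonicity guarantee, but the training
objective is non-decreasing per round on the test fixtures.

**Thresholds.** Every method converts scores to labels by a threshold that
minimises the training error over the candidate set {midpoints of
consecutive sorted distinct scores} plus one surrogate beyond each extreme
(the two trivial rules). Ties prefer the candidate with the larger margin
to the nearest score, then the smaller value; a score exactly at the
threshold predicts +1. An exhaustive-scan oracle in the tests confirms
optimality.

## Metrics

Empirical AUC is the pair-counting statistic with ties credited as full
successes (`H(0) = 1`), matching the Heaviside convention used throughout;
a `ties='half'` Mann–Whitney variant is available and every result records
which convention produced it. The smoothed AUC converges to the empirical
AUC as `σ → 0` on tie-free scores (checked at `σ = 1e-6` to 1e-9).

## Window families and resampling stability

Genes are ranked by `|Pearson r|` with the outcome (absolute value, so
markers of both classes rank; a signed option exists) or by folded
per-gene AUC `max(A, 1-A)`. Ties keep input order, making the ranking
deterministic and permutation-equivariant. The window family walks the
top of the ranking in inclusive windows — width 70, step 5 over 230 ranked
genes gives the 33 windows from ranks 1–70 to 161–230 — and every window
is fitted on training data only and evaluated on both splits. Window
failures are recorded per (window, method) and do not stop the sweep.

Stability is measured by drawing without-replacement patient subsamples
(default 50 of 78, 100 draws), re-ranking on each draw, and recording each
gene's top-70 inclusion frequency. Single-class draws are rejected and
redrawn, with an error after 100 consecutive rejections. The companion
prediction analysis refits the classifier per draw on the subsample's own
top-k genes and evaluates on the complementary patients by default (the
only data available without an external test set; evaluating on a fixed
external pair is an option).

## Clustering and BHI

Samples (or genes, for heat-map leaf order) are clustered by complete
linkage on the correlation distance `1 - r`, via scipy's agglomerative
implementation, and cut to exactly K clusters with labels renumbered in
order of first appearance. K defaults to the number of distinct category
labels (2 for binary statuses) and is configurable. BHI averages, over
clusters, the fraction of ordered within-cluster pairs sharing a category
label. The definition divides by `n_k(n_k - 1)`, which is zero for
singletons; singleton clusters contribute 0 to the sum while still
counting in K, deliberately penalising fragmented clusterings. BHI is
bounded in [0, 1] and attains 1 exactly on label-pure clusterings with all
cluster sizes ≥ 2 — both facts are verified by randomised search in the
tests and the acceptance script.

## Mutual coherence

`μ(X)` is computed as the maximum absolute cosine between distinct gene
columns. Two modes exist because the uncentred cosine and the Pearson
correlation between genes differ: `raw_cosine` (default for `μ` itself)
uses columns as-is, `pearson` (default for the distribution curve) centres
them first; every report records its mode. Cosines within 1e-12 of 1 are
snapped to exactly 1.0 so that collinear columns attain the upper bound in
floating point (the collinearity snap). The full sorted pair list is kept
up to 5×10⁶ pairs; beyond that a 10⁴-bin histogram plus the exact top-100
pairs bound memory. The sorted curve is resampled at evenly spaced
quantiles so gene sets with different pair counts overlay. The sparsity
certificate declares a k-sparse solution of `Xβ = b` sparsest-possible iff
`k < (1 + 1/μ)/2`; with `μ = 0` the certificate is vacuously true for any
finite k (documented convention). The linear system itself is never
solved — no right-hand side exists to solve for; the bound serves as a
diagnostic of how little support the data can certify.

## Synthetic studies

The generator emulates the statistical structure the diagnostics feed on,
not microarray physics (no probe effects, intensity distributions, or
missingness). Per sample: a latent subtype (uniform over `n_subtypes`);
an outcome whose positive rate is 0.8 in the designated poor-prognosis
subtype and solved for the remaining subtypes from the requested marginal
balance (defaults: 3 subtypes, balance 0.4, hence rates 0.8/0.2/0.2); gene
values built from an equicorrelated Gaussian factor per block
(`√ρ·u_b + √(1-ρ)·ε`); a mean shift of ±effect/2 on the informative genes
by class; a block-by-subtype mean offset drawn once from
`N(0, subtype_effect²)`; and ER/PR statuses equal to the subtype's nominal
status (poor subtype negative) flipped with probability
`1 - hormone_coupling`. The offsets are what let clustering-by-expression
recover subtypes and hence hormone status — without them the latent
subtype would be invisible in `X` and the clustering diagnostics would
have nothing to find.

Defaults are the study conditions every stochastic test runs under: 97
samples (split 78/19), 300 genes, 20 blocks of 10 at ρ = 0.9, 90
informative genes at effect 0.6 SD, hormone coupling 0.9, subtype effect
1.0. These sizes keep the full suite and pipeline in seconds while
preserving the phenomena of interest: block correlation produces pairwise
|r| up to ≈0.98 and mutual coherence near 1; the diffuse weak signal makes
dozens of windows predict comparably and the top-70 ranking unstable under
resampling. The real study's subtype proportions are not known; the
defaults are choices, not calibrations. `inject_collinear_pair` rewrites
one gene as an exactly-`r`-correlated mixture of another (fresh noise
orthogonalised against the source column, original mean/SD restored) as a
fixture for near-duplicate genes.

What passing tests show — and do not. The qualitative reproductions
(many near-equivalent windows; wide spread of inclusion rates; high
coherence inside correlation-ranked sets) demonstrate that the
implementation produces these phenomena under the generative mechanism
believed to drive them, at desk scale. They do not certify the real
study's numeric values (BHI levels, the exact coherence 0.984, test AUCs),
which require the original data; the pipeline accepts that data as TSV and
computes the same quantities.

## Reproducibility and numerics

All randomness flows from integer seeds through `numpy.random.default_rng`;
the pipeline derives stage seeds from one master seed by fixed offsets
(simulate +0, split +1, classify +2, stability +3, resample +4, mod 2³¹)
and re-running a config reproduces byte-identical artifacts. Degenerate
inputs have defined behaviour throughout: constant genes contribute no
stumps or learners and rank at score 0; constant samples make correlation
scores an error; exponential-loss evaluation is log-sum-exp guarded;
distance matrices are symmetrised against rounding and clipped to [0, 2].

## Known limitations

* The upstream filtering step that produces the analysable gene set is out
  of scope; the package trusts its input matrix.
* AUCBoost's per-round cost is O(candidates × class-pair count); the
  pipeline's default window sweep therefore uses the linear methods and
  AdaBoost, with AUCBoost available per-window via configuration.
* `hierarchical_cluster` requires the maxclust cut to yield exactly K
  clusters and errors on pathological tied-height trees rather than
  silently returning fewer clusters.
* BHI is reported for whatever K is chosen; it is not maximised over K.
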