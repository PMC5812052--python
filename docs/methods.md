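# Methods

## Model

For one microbial feature, the read count of subject *i* in phenotypic group
*k* ∈ {1, 2} at collection time *t* is modeled as negative binomial,
Y_tki ~ NB(α_k, p(t,k)) with shape α_k > 0 and success probability p(t,k),
observations independent given the curves.  The group trajectory is the
logit curve η(t,k) = log p/(1−p); the mean trajectory is
μ(t,k) = α_k (1−p)/p = α_k e^{−η(t,k)}, so the model is equivalently a
log-link NB regression with variance μ + μ²/α.  Assumptions worth stating
explicitly:

* counts (after between-sample normalization) are NB at every time point —
  the `distfit` module exists to check this assumption per feature;
* the mean trajectory is smooth in time; there are no subject-level random
  effects in the model (within-subject correlation is instead respected in
  the resampling design and in cross-validation, see below);
* exactly two groups; each subject belongs to one group; time is any
  non-negative real in a unit of the user's choosing.

α is treated as a continuous positive parameter estimated by profile
likelihood (the counting-based integer restriction would add nothing and
breaks on normalized fractional counts).  Groups are fitted independently;
`SmootherConfig.share_alpha` pools the dispersion across groups when set.

## Curve estimation

Each group's curve minimizes the penalized negative log-likelihood
−L + λ·J(η) with the cubic smoothing-spline roughness J(η) = ∫ η″(t)² dt.
Because η and log μ differ by the constant log α, the same penalty applies
to the log-mean curve, and the fit is computed in that parameterization: it
decouples the curve from the dispersion, whose profile updates otherwise
crawl along a likelihood ridge.

* **Spline space.** Cubic B-splines with knots at the group's distinct
  observed times; the penalty matrix ∫B″ᵢB″ⱼ is assembled exactly with
  2-point Gauss–Legendre quadrature per inter-knot interval (the integrand
  is piecewise quadratic).
* **Optimization.** Penalized Fisher scoring (IRLS) with step halving, so
  the penalized objective is monotone; observations sharing a time point are
  aggregated, making each iteration O(K²) in the number of distinct times
  rather than the number of samples.  Coefficient updates alternate with
  Newton updates of log α on the profile likelihood.  Convergence: relative
  objective change < 1e-8 (cap 200 inner iterations, 25 outer
  alternations); initialization is the intercept fit, so fitting is fully
  deterministic.  Fits that stop without meeting the tolerance are flagged
  `converged=False`.
* **Smoothing parameter.** λ is selected from a 10-point log-spaced relative
  grid (1e-4…1e4) by K-fold cross-validation (default K = 5) maximizing
  held-out NB log-likelihood, with leave-one-subject-out available
  (`cv="loso"`).  The grid is rescaled per fit by n·tr(BᵀB)/tr(Ω) so that
  its ends bracket the interpolation and the linear-fit regimes for any
  sample size and time spacing.  **Folds are blocks of whole subjects**
  (sorted subjects dealt round-robin): with strong serial correlation within
  a subject (the simulator uses ρ = 0.9), sample-wise folds leak
  information between train and test and push λ to the interpolation
  corner.  Near-ties on the CV score go to the larger λ.
* **Degenerate input.** A group with < 4 observations, < 3 distinct times,
  or all-zero counts is refused and the feature is reported untestable (an
  all-zero curve would make the area ratio 0/0 on every interval).
* **LOWESS backend.** `smoother="lowess"` replaces the NB spline with
  statsmodels' locally weighted regression (default span 0.67), clipped
  below at 1e-6 so areas stay well-defined; it satisfies the same curve
  interface, which is exactly what the benchmark uses to compare the two
  backends.

## Interval testing

The testing grid spans the **overlap range** [max of group start times,
min of group end times]; with integer times the grid has unit spacing,
otherwise 20 equally spaced points.  Per unit interval the statistic is the
area ratio AR = (A₁−A₂)/max(A₁,A₂) ∈ [−1,1] of the areas under the two
fitted mean curves (7-point Gauss–Legendre per interval for splines, exact
piecewise-linear integration for LOWESS).  An interval with both areas zero
is untestable and excluded from the multiple-testing family rather than
given p = 1.

The null is built by permuting **subject**-to-group assignments preserving
group sizes — a subject's samples move as a block, so within-subject
correlation survives under the null (`--permute-samples` switches to
sample-level shuffling).  Both curves are refitted per permutation, reusing
the λ selected on the observed data for each group slot (so observed and
permuted statistics go through the identical procedure conditional on λ;
re-running CV inside every permutation would cost ~50× more and add only
selection noise), with α re-profiled each time.  A permuted group can span
less time than the grid; its curve is then extended as a constant, which
keeps every permutation's AR defined on every interval.  Permutations whose
refit fails are discarded; a feature is untestable if more than half fail.

p-values are two-sided on |AR| with the add-one rule
p = (1 + #{|AR_null| ≥ |AR_obs|}) / (1 + n_valid), which cannot return 0 and
keeps BH's ordering guarantees; `pool_null` compares each interval against
all intervals' pooled draws instead.  BH runs per feature across its
intervals by default (`adjust_scope="global"` adjusts across all features ×
intervals jointly).  Adjacent significant intervals with the same dominant
group are additionally reported merged into spans.

## Simulator

The generator reproduces the benchmark conditions the detector is scored
under:

* **Mean patterns.** Differential features: group B follows
  μ_B(t) = 30 + 10·sin(πt/20) on t ∈ [0,20]; group A is μ_B times a C¹
  gain built from piecewise-cosine ramps (width 1) that rises to 2.5 inside
  each differential region [1,5], [8,13], [15,20] and is exactly 1 on
  [5,8] and [13,15].  The ramps complete within one unit interval so every
  truth-positive interval carries substantial separation.  Null features
  use one constant level per feature, drawn from Normal(30, 5) truncated
  below at 5, shared by both groups.
* **Marginals.** NB with mean μ(t) and size 40/μ(t) (variance μ + μ³/40),
  Poisson with λ = μ(t), or zero-inflated Poisson with Poisson part μ(t)
  and inflation π₀ = 0.3.
* **Correlation.** A latent stationary standard-normal AR(1) series with
  ρ = 0.9 per (feature, subject) is pushed through Φ and then the target
  marginal's quantile function (Gaussian copula).  The transform is
  monotone; the achieved count-scale lag-1 correlation is somewhat below ρ
  and is a property of the construction, not a target.
* **Designs.** `consistent`: 15 subjects per group, all sampled at
  t = 0…20.  `inconsistent`: per feature, group A keeps 8 randomly chosen
  subjects with 11 randomly chosen times each and group B keeps 6 subjects
  with 8 times each — unequal subjects per group, unequal samples per
  subject, uneven spacing.  This per-subject reading is the one under which
  the reference benchmark performance is actually attainable: a group with
  only ~10 samples in total over 21 time points cannot support interval-level
  inference at the reported accuracy, by any method.  A flag freezes one
  subsampling across features.
* **Ground truth and scoring.** Truth masks live on the 19 unit intervals
  of [1,20]; 14 are differential for DA features.  Scoring counts, per
  feature, called/uncalled intervals against the mask (intervals outside a
  feature's overlap range, or of an untestable feature, count as not
  called); sensitivity = TP/(TP+FN) over truth-positive intervals,
  specificity = TN/(TN+FP) over truth-negative ones, reported as mean ± SD
  across features.

What the simulator deliberately does **not** emulate: library-size
variation between samples (so benchmarks run unnormalized), compositional
coupling between features, subject-level random effects beyond AR(1)
serial correlation, and taxonomic correlation structure.  Passing the
benchmark therefore demonstrates interval-level error control and power
under the stated noise model, not under every failure mode of real data.

## Distribution checker

Per feature and candidate family (NB, ZIP, Poisson, lognormal, exponential,
half-normal, normal): maximum-likelihood fit (NB profiled in the shape on
the log scale; ZIP profiled in the rate with the closed-form inflation
weight; lognormal on counts + 1 to survive zeros), then a **two-sample** KS
test between the observed counts and a comparator sample drawn from the
fitted distribution (comparator size = observed size unless overridden).
The sampled-comparator construction, rather than a one-sample KS against the
fitted CDF, is deliberate — it is the procedure whose adequacy percentages
the package reports, and it inherits the mild conservatism of two-sample KS
under discrete ties.  BH adjustment runs within each family across
features; a pair is adequate when the adjusted p-value exceeds 0.05.  The
checker reports; it does not (yet) switch the test's model automatically.

## Problem sizes and reproducibility

The test suite runs the benchmark scenarios at 30+30 features with 200
permutations, the type-I-error check at 100 null features, and the full
acceptance script at 100+100 features with 200 permutations — a deliberate
desk-scale rendition of the reference setup (500+500 features, 1000
permutations) chosen so the whole suite completes on one CPU in minutes.
Every random stage (simulation, permutations, KS comparators) draws from
`numpy` Generators seeded from a single master seed; per-feature seeds are
derived with `SeedSequence(master, feature_index)`, so results are
bit-reproducible and independent of execution order.

## Known limitations

* **Heavy overdispersion caps power.**  With the NB size rule 40/μ(t) and
  mean levels around 30–100, the per-observation standard deviation is of
  the order of the mean itself; a back-of-envelope oracle test (true curves
  known) then has per-interval power near 50%, and the spline detector
  accordingly recovers only a fraction of truly differential intervals in
  that regime.  The same mechanism depresses sensitivity under
  zero-inflation at high means, where an inflated zero is an extreme
  outlier that collapses the fitted dispersion and widens the permutation
  null.  Power figures from the Poisson scenarios are the informative ones
  for mildly dispersed data.
* Sparse sampling over long spans leaves the spline poorly determined
  between observations; intervals there are tested but should be read with
  caution.
* No confounder covariates (age, sex, …) and no >2-group designs.
* The permutation test conditions on the observed λ; features whose CV
  selection is unstable inherit that instability in both the observed and
  null statistics symmetrically.
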