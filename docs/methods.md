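# Methods

This note documents the statistical procedures the package implements,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## Problem setting

Given an n × p expression matrix (samples × features, n ≪ p) and binary
class labels, the goal is to (i) flag *influential samples* — samples
whose values or label deviate from their class's bulk strongly enough
to distort a fitted classifier — and (ii) select a small, stable set of
class-discriminating features.  Both tasks are performed by a consensus
over three robust sparse classifiers chosen to be methodologically
disjoint: a PLS-type M-estimator (SPRM-DA), a trimmed sparse clustering
method (RSKC), and a trimmed penalized likelihood method (enetLTS).
Because the three rest on different assumptions, agreement between them
carries evidence that a flag or a selected feature is not an artifact
of one model family.

## Pre-processing (`io_prep`)

Constant features are removed; features are optionally pre-screened by
univariate ROC-AUC importance, symmetrized as max(AUC, 1 − AUC) so both
up- and down-regulated features count (AUC is computed rank-based with
average ties, so the screen is invariant to monotone transforms); and
values are moved to log2(x + 1), the usual convention for FPKM-type
RNA-Seq values (base and offset configurable).  The screen's `keep`
parameter is free: the original application kept 16,600 of 19,688
features, a bound imposed by one classifier's capacity rather than by a
statistical rule.

## SPRM-DA (`sprm`)

The binary response is encoded as centred group codes (class 1 →
n0/n, class 0 → −n1/n), features are robustly standardized by column
median and MAD (consistency factor 1.4826, floor 1e-8 against
near-constant features).  The fit alternates (a) case-weighted sparse
NIPALS PLS — each direction vector soft-thresholded at eta·max|w| and
renormalized — with (b) recomputation of case weights as the product of
a residual factor f(r/σ̂) and a leverage factor f(d/median d) measured
in latent-score space, where f is the Fair weight 1/(1 + |z|/c)² with
c = 4 (Huber optional; a constant-weight option exists for reductions
to plain PLS).

Numerical choices that matter:

* **Initialization**: case weights start from leverage distances only.
  Residual-based initialization is standard for a continuous response
  but degenerate here — the encoded response takes two values, so its
  median coincides with the majority code and the MAD collapses to
  zero, which would annihilate one class at the first iteration.
* **Scale guard**: the residual scale estimate is floored at 1e-3 times
  the response range; without it the reweighting spiral (smaller scale
  → harsher weights → fit concentrates → smaller scale) can collapse
  onto a degenerate subset.
* **Damping**: the case-weight update is averaged with the previous
  weights (factor 0.5).  An undamped update can lock into a two-cycle
  of the soft-thresholded support and never meet the coefficient
  tolerance (default 1e-4 relative, max 150 iterations; non-convergence
  returns the last iterate with a warning rather than failing).

Outlyingness is 1 − case weight: case weights are the method's inherent
robustness measure.  Prediction assigns the nearest case-weighted class
centroid in score space; an exact tie goes to class 0.

## RSKC (`rskc`)

Alternating optimization: (a) trimmed Lloyd iterations in the
weighted-feature space, trimming the ⌈αn⌉ cases farthest from their
center (O_W); (b) a second trim in the *unweighted* space (O_E) with
centers updated on untrimmed cases; (c) feature weights maximizing the
weighted between-cluster sum of squares subject to ‖w‖₂ ≤ 1 and
‖w‖₁ ≤ s (soft-threshold with bisection; when exactly tied
between-cluster values make the unit-sphere solution infeasible the
weights are backed off to the L1 boundary inside the L2 ball).

Two design points discovered the hard way:

* **Restart selection minimizes the trimmed weighted within-cluster
  SS**, not the between-cluster objective.  Selecting restarts on
  between-cluster SS rewards the degenerate solution that splits a
  gross outlier into its own cluster (its between-cluster SS is
  enormous), which is precisely what trimming exists to prevent.
* **Outlyingness is the unweighted squared distance to the nearest
  center** — the O_E criterion.  The weighted distance is blind to
  shifts on zero-weight features, so it cannot see the coordinate
  outliers the second trimming stage is designed to catch; with the
  unweighted score the method detects expression-shift contamination
  while remaining near-random for label flips (it never sees labels).

Initialization draws K pairwise-distinct samples per restart *by sample
identifier*, so permuting the row order permutes all outputs
consistently.  The L1 bound can be tuned by a permutation gap statistic
(feature columns permuted independently, default 25 permutations);
α defaults to 0.1.  For cluster-vs-class comparisons, the 2-cluster
assignment is mapped to labels by whichever of the two mappings
minimizes misclassifications (ties keep the identity mapping).

## enetLTS (`enetlts`)

Elastic-net-penalized logistic regression on the best h-subset
(default h = ⌈0.75 n⌉): elemental starts of three cases per class are
concentrated by C-steps (penalized fit on the current subset → new
subset = the h cases of smallest deviance, stratified so both classes
stay represented) until the subset is stable; the best objective is
kept, followed by a reweighting refit on all cases whose standardized
Pearson residual is below the 0.9875 normal quantile.  The penalized
solves are ordinary convex problems and are delegated to scikit-learn's
SAGA elastic-net logistic solver (glmnet-scale λ mapped via
C = 1/(h·λ); an unpenalized lbfgs fast path is used for λ ≤ 1e-7).
When no λ is given it defaults to 0.1 times the smallest penalty that
zeroes all coefficients, the usual path heuristic; cross-validated
selection over a small (α, λ) grid on the final consistent subset is
available for the main ensemble run.  Deviance residuals drive the
C-steps; standardized Pearson residuals drive the reweighting and are
the outlyingness score.  Features are standardized once by column
median/MAD so scores are scale-invariant.

## Rank-product consensus (`rankprod`)

Ranks are descending in outlyingness with average ties, so each rank
vector sums to n(n+1)/2 exactly.  RP(i) = ∏ R_l(i).  The null treats
the k ranks as independent uniforms on {1,…,n} — the convention of the
rank-product test, deliberately ignoring the without-replacement
dependence within a ranking.  p-values are **exact**: the number of
k-tuples with product ≤ RP is counted by a capped divisor-sum recursion
(≈10⁵ integer operations for k = 3, n ≈ 1000, memoized), divided by
n^k.  Tie-averaged non-integer rank products are handled by counting
products ≤ ⌊RP⌋ (integer tuples cannot fall between).  A gamma-tail
approximation (−log ∏(U/n) ~ Gamma(k, 1)) is available behind a flag
for large k; it is accurate in the bulk but loose deep in the tail,
which is why the exact count is the default.  q-values are
Benjamini–Hochberg by default, with Storey's plug-in estimator (λ =
0.5) as an option; samples with q below 0.05 are called influential.
The published q column of the original application is not exactly
reproducible by either option, so q-values are configurable and only
the p-values are treated as exact references.

## Ensemble, bootstrap

The ensemble requires exactly three rankings: if any method fails to
fit or selects no features the run aborts naming the method — there is
no silent two-method fallback, because the consensus null is defined
for k = 3.  Hyperparameter optimization (when enabled): SPRM by
stratified 5-fold CV misclassification over (components, eta) with ties
resolved toward the sparser model; enetLTS by its internal CV; RSKC's
L1 bound by the gap statistic and α by agreement of mapped cluster
labels with a reference labelling (the observed labels by default).

The validity check partitions each class into m near-equal blocks
(m = 5 by default; sizes differ by ≤ 1, remainder blocks chosen by a
seeded draw) and fills each block to size n by class-stratified
sampling with replacement from all samples, so every sample occurs in
at least one block and class counts are preserved exactly.  Duplicated
samples are genuine multiset duplicates, and block consensus p-values
use n = block size with duplicates counted individually.  Blocks are
refitted with the main run's hyperparameters; a failed block is
recorded, not fatal.

## Synthetic data and what passing tests show (`simulate`)

The generator emulates a two-class expression study: balanced classes,
unit-variance Gaussian features, a sparse informative set (5% of
features by default) whose class-1 mean is shifted by `effect_size`
(default 1.0).  Three contamination scenarios plant ground-truth
outliers: label switching of 5% or 15% of samples, and +3 per-feature-SD
shifts on 15% of features for 5% of samples (SDs computed on the
uncorrupted matrix over all samples; shifted features and samples are
drawn uniformly, so overlap with the informative set is incidental).
Defaults are n = 200, p = 3200; the bundled tests and the acceptance
script run at p = 800 with the same n, which preserves the
signal-to-dimension regime at a fraction of the cost, and the study
uses fixed, field-typical hyperparameters per method rather than
re-optimizing per scenario, keeping the three methods comparable
across scenarios and seeds.

What the generator does **not** emulate: count-based mean–variance
relationships, feature–feature correlation blocks, library-size and
batch effects, or class imbalance.  Passing the simulation tests shows
that the consensus correctly fuses heterogeneous outlier evidence under
idealized noise — not that the method's error rates transfer to real
RNA-Seq.  Under this reconstructed signal strength the shifted-sample
subgroup is strong enough that the supervised methods also detect it,
and at some seeds RSKC's clustering advantage on that scenario (seen in
the original study) does not materialize; the qualitative invariants
that are asserted are the robust ones: RSKC is near-random on label
switches, the consensus is never worse than the weakest member per
scenario, and on average it beats at least two of the three members.

Rankings are evaluated by ROC/AUC against the planted truth (ties count
one half); the consensus is scored by −log RP, which orders samples
identically to RP at lower cost than p-values.

## Known limitations

* SPRM coefficients are reported on the standardized scale; no
  back-transformation to raw expression units is provided.
* RSKC with the fixed study L1 bound (√p/2) often keeps all feature
  weights positive, making its "selected set" dense; sparse selection
  for RSKC requires the gap-statistic tuning of the main run.
* The exact p-value recursion assumes k small (it is O(n²)-ish per
  distinct RP value for k = 3); for k ≳ 6 use the gamma approximation.
* Only binary classification and K = 2 clustering are supported.
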