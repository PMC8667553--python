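# Methods

This note records the model, the conventions and defaults the package
commits to, what the synthetic generator does and does not emulate, and the
design choices made where more than one reasonable option existed.

## Model and objective

The single-cohort model is Cox proportional hazards with a latent group
lasso penalty.  The negative log-partial likelihood uses risk sets
`{j : Y_j ≥ Y_i}`; tied event times share one risk set (Breslow convention),
which is the literal reading of the partial likelihood above and keeps the
objective simple and smooth.  Log-sum-exp terms are max-shifted, and the
risk-set denominators are suffix cumulative sums over time-sorted samples,
so one evaluation costs O(n log n + nM).

Overlapping pathways are handled by gene duplication: each (pathway, gene)
incidence becomes its own latent column, an exact copy of the standardized
expression column.  The group blocks are then disjoint by construction, and
a latent coefficient vector collapses to gene space by summing copies —
hazard scores are identical in either space by linearity (tested).

The group penalty is `λ Σ_g |g|^w ‖β_g‖₂` with w = 0.5 by default.  The
√|g| weighting is the standard group-lasso choice that makes per-group
penalties comparable across group sizes; `w` is exposed in `PenaltyConfig`
because the choice only rescales the useful λ range, not the model class.

### Coupling penalty

The two-cohort coupling is
`μ Σ_g |g|^w √((A_g¹²)² + (A_g²¹)²)` with
`A_g^{ij} = ‖β_g^i − β_g^j (‖β_g^i‖/‖β_g^j‖)‖`, each term gated by
indicators `‖β_g^i‖ > ε` for both cohorts (ε = 1e-8 by default).  Properties
relied on downstream, all covered by tests:

* symmetric in the two cohorts;
* exactly zero when blocks are positively proportional group by group, so a
  pathway may be differentially *scaled* across cohorts at no cost;
* a pathway inactive in either cohort contributes nothing (indicator
  gating), and zeroing a block can never increase the penalty;
* homogeneous of degree 1 under a common positive rescaling.

The two cross terms are combined as the root of the sum of squares; the
difference vectors are computed directly (not via the expanded quadratic
form) so proportional blocks give a cancellation-free zero.  Three simpler
couplings kept from preliminary work — plain block difference, cosine
distance, and unit-vector difference — are available as
`coupling_variant={'abs_difference','cosine','normalized_difference'}`; the
unit-vector variant is implemented as `‖β_g¹/‖β_g¹‖ − β_g²/‖β_g²‖‖` with
zero blocks skipped.

The ε indicator tolerance is deliberately distinct from the fitter's 0.001
truncation threshold: ε guards the loss evaluation against floating-point
near-zeros, while truncation is a post-hoc model-selection rule.

## Optimizer

Minimization is Adam (β₁ = 0.9, β₂ = 0.999) on the composite objective with
hand-derived analytic (sub)gradients; subgradients at zero coefficients or
zero blocks are taken as zero, and coupling terms gated off by the
indicator contribute zero gradient.  All gradients are verified against
central finite differences in the test suite.

A plain first-order method oscillates around the nonsmooth minima of
L1-type penalties with amplitude on the order of the learning rate, which
would leave "zero" groups hovering above the 0.001 truncation threshold.
The learning rate therefore decays exponentially from `learning_rate`
(default 0.05) to `learning_rate · lr_final_fraction` (default ×0.01)
across the run, putting the terminal oscillation well below the threshold.
For the same reason the plateau-based early-stopping rule is disabled by
default (`convergence_tolerance = 0`): the loss flattens long before the
rate has decayed, and stopping there produces noisy coefficients.  With a
fixed iteration budget, fits are deterministic given seed, config and data
(bit-identical, tested).

Initialization is N(0, init_scale²) with init_scale = 0.01 — near zero to
suit sparse targets but off the exact nonsmooth point.  After optimization,
any group whose coefficients are all below 0.001 in absolute value is set
exactly to zero; for gene-level lasso each coefficient is its own group.
In the joint fit, cohort 1 initializes from `seed` and cohort 2 from
`seed + 1`; since Adam updates are coordinate-separable, at μ = 0 the joint
trajectory coincides with two independent single fits at those seeds.

λ_max — the smallest λ at which β = 0 is stationary — is computed in closed
form from the subgradient condition at the origin,
`λ_max = max_g ‖∇l(0)_g‖₂ / |g|^w` (for plain lasso, `‖∇l(0)‖_∞`).  This is
exact and replaces any iterative search for the top of the λ path.

## Standardization and evaluation conventions

* Genes are z-scored with the **sample** sd (ddof = 1); this convention is
  recorded in fit metadata.  Held-out data is always standardized with
  training-set moments, so test columns need not be centred — this is
  required for honest test c-values.  Zero-variance genes become all-zero
  columns and are flagged rather than dropped, keeping gene indexing stable
  across resampling.
* Concordance follows the Harrell convention: a pair is comparable when the
  strictly earlier subject had an event, or at tied times when exactly one
  subject had an event (the event subject counts as earlier, since a
  censored time is a lower bound).  Tied event times with two events,
  censored-before-event pairs and censored-censored pairs are not
  comparable; tied scores on a comparable pair count 0.5.  An all-constant
  score vector therefore scores exactly 0.5.  Other published c-statistics
  differ in their tie handling, so absolute c-values are only comparable
  within this package.
* Tucker congruence is the normalized inner product averaged over all
  unordered pairs of coefficient vectors, compared in latent space (the
  deterministic design construction guarantees a common coordinate system
  across splits).  A pair containing an all-zero vector contributes φ = 0
  and is logged.  For the significance test on congruence, splits are
  paired (1,2), (3,4), … so no fitted β enters two pairs.
* The paired t-test is the two-sided one-sample t-test of the per-split
  differences against zero; zero-variance differences are an error at the
  statistics layer (the experiment drivers report t = 0, p = 1 in that
  fully-degenerate case).  Families of p-values are adjusted with
  Benjamini–Hochberg.

## Hyperparameter search

Single-task λ comes from a K-fold cross-validated grid search maximizing
mean validation c-value (10 folds by default), over a log-spaced grid below
the closed-form λ_max (10 points spanning [1e-3, 1]·λ_max by default);
exact ties break toward the larger, sparser λ.  For the coupled model, 30
triples are drawn — λ_j ~ N(λ_j⁰, (0.1 λ_j⁰)²) around the single-task
optimum, clipped at a 1e-6 floor so the draw count is preserved, and
μ ~ half-normal with sd 0.5 — and each is scored by per-task cross-validated
c-value; the best triple is kept per task.  Repeated evaluation uses random
80–20 train-test splits: 100 by default for single-task comparisons and 30
for the multi-task protocol, with all split, fold and fit seeds derived
deterministically from one user seed.

## Synthetic data generator

The generator emulates a paired expression–survival study: two cohorts of
300 and 200 patients by default, a configurable gene universe (2,000 genes
at desk scale; ~10,000-gene runs are a config change), a synthetic pathway
collection (20 pathways of 25 genes, adjacent pathways sharing 5 genes so
the latent expansion is exercised), and survival driven entirely by two
true pathways per cohort with one shared — the regime where cross-cohort
coupling has something to transfer.

* **Expression** is multivariate normal.  The default `block` model gives
  genes of a pathway an equicorrelation ρ = 0.5 via a shared factor,
  mimicking the strong within-pathway collinearity of tumour expression
  data; `independent` and low-rank `factor` models are available, and
  user-supplied mean/covariance moments can be plugged in directly (a
  non-positive-definite covariance is rejected).
* **True coefficients** are the first-principal-component loadings of each
  true pathway's gene columns over the pooled cohorts (so the shared
  pathway has identical loadings in both cohorts), zero elsewhere.  PC sign
  is fixed by making the largest-magnitude loading positive.
* **Survival**: events are i.i.d. Bernoulli(0.7).  Since the Cox model only
  sees the ordering of times, the base time is the rank-preserving positive
  transform `exp(−score/sd(score))` of the hazard score.  Censored patients
  then have their time multiplied by `U^(shrink·q_i)` with U ~ Uniform(0,1)
  and q_i the fraction of patients with a strictly higher score: the
  recorded censoring time drops below the latent death time, with low-risk
  patients shrunk the hardest.  The multiplicative-power form is one
  consistent choice among many; it preserves positivity and the
  lower-bound semantics of censoring, and is config-exposed.

What the generator does **not** emulate: real tumour covariance structure
(it is parametric unless moments are supplied), batch effects, non-normal
expression margins, informative censoring, or any relationship between
censoring and follow-up time.  Passing tests on this generator demonstrate
algorithmic correctness and the qualitative behaviour of the penalties —
support recovery, the direction of the coupling effect — not expected
effect sizes on real cohorts.

## Problem sizes in tests and the acceptance script

The repeated synthetic study (`synthetic_multitask_study`) runs 20
independent seeds of the default 2,000-gene, 300/200-patient pair with a
trimmed search protocol: 3 CV folds, a 6-point λ grid over [0.02, 1]·λ_max,
6 random (λ1, λ2, μ) draws, 3 evaluation splits per seed, 500-iteration
fits inside searches and 1,200-iteration final fits.  These sizes keep a
full study to a few minutes of desk compute while leaving the generator's
study conditions untouched; every knob accepts larger values.

## Known limitations

* Adam with truncation is not an exact solver: selected-group counts along
  a λ path can show single-step non-monotonic blips from optimizer noise,
  and coefficients match proximal solutions only to optimizer tolerance.
* The coupling term is non-convex (through the norm ratios and
  indicators), so the joint fit can depend on initialization; the fixed
  seeding makes this reproducible rather than eliminating it.
* The λ-grid span and the half-normal μ scale are heuristics; on data whose
  loss scale differs wildly from standardized expression they should be
  revisited.
* Joint fitting of more than two cohorts is out of scope (the number of
  coupling terms and hyperparameters grows quadratically).
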