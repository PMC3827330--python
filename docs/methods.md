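# Methods

## The problem

Longitudinal studies of educational attainment — secondary-school grades,
undergraduate examination marks, post-graduate professional examinations —
face three systematic distortions when ordinary Pearson correlations are
used to quantify how strongly each stage predicts the next:

1. **Ceiling censoring.** Grade tariffs have a maximum (best three
   A-levels cap at 30 points under the pre-2010 scheme), and in strong
   cohorts a large share of candidates sit exactly at the ceiling. The
   observed distribution is left-skewed and under-dispersed, and the
   observed correlation with any other measure is biased toward zero.
2. **Grouping.** Some outcomes are recorded only as a few ordered
   categories (distinction / satisfactory / resit / fail) or as a binary
   state (on the specialist register or not). Correlations computed on
   category codes are attenuated relative to the latent association —
   the classical tetrachoric/polychoric/biserial problem.
3. **Selection and selective uptake.** Entrants are selected on early
   scores (restriction of range), and only stronger students attempt
   later optional examinations, so later columns are missing
   not-at-random.

`cohortpath` models each pair of measures as a latent bivariate normal
and estimates the latent correlation ρ from whatever was actually
observed, corrects composite correlations for measurement unreliability
with classical test theory, and summarises the stage-to-stage structure
as a path model fitted by backwards elimination.

## Latent-correlation model

For a pair (X, Y) latent bivariate normal with means μ, SDs σ and
correlation ρ, every observation on a margin contributes either

* a **point** (continuous value observed exactly, standardised to
  (v − μ)/σ),
* a **tail interval** (a censored value at a declared ceiling c maps to
  [(c − μ)/σ, ∞); a floor maps to the lower tail), or
* a **category interval** (category k of a grouped margin maps to
  (τ_{k−1}, τ_k] with strictly increasing thresholds τ; grouped margins
  are identified by fixing μ = 0, σ = 1).

The pairwise log-likelihood sums, over pairwise-complete pairs:
bivariate normal log-density (point–point); marginal log-density plus the
conditional normal interval probability (point–interval); and the
bivariate rectangle probability (interval–interval). Rectangle
probabilities use the Genz/Drezner–Wesolowsky Gauss–Legendre algorithm
(absolute accuracy well below 1e-8 over the full correlation range; the
test suite checks partitions of the plane sum to 1 within 1e-8 and the
closed-form orthant identity P(X>0,Y>0) = 1/4 + arcsin(ρ)/2π).

The censoring bound is part of the variable's declared metadata
(`VariableSpec.ceiling`/`floor`), never inferred from the data; values
observed exactly at the bound are censored, values strictly inside are
exact points.

### Sampling

The posterior is sampled with DRAM (Delayed-Rejection Adaptive
Metropolis):

* **Parameterisation** — μ, log σ, atanh ρ, and (τ₁, log successive
  threshold gaps): an unconstrained vector, so the Gaussian random-walk
  proposal never leaves the valid region. Priors are flat on these
  coordinates, mimicking maximum-likelihood-style use of MCMC; no
  substantive prior information is introduced.
* **Adaptation** — the proposal covariance is the scaled empirical
  covariance of the chain history (2.38²/d), updated every 10 steps
  after a non-adaptive first 10% of the chain.
* **Delayed rejection** — one fallback stage with the proposal Cholesky
  shrunk by 0.2, with the standard DR acceptance correction. This keeps
  acceptance healthy in the early phase when the initial proposal scale
  is wrong.
* **Chain conventions** — default chain length 5000 (10000 for hard
  problems); the estimate is the mean of the final 2000 draws, the
  standard error their SD, and the 95% interval the 2.5th/97.5th
  percentiles of those draws. Burn-in is implicit in summarising only
  the final window. A Geweke-style z on the first versus last quarter of
  the window is reported as an ergodic-stability diagnostic (|z| < 3
  passes; a constant chain is defined stable with z = 0).
* **Initialisation** — naive Pearson (rank-based for grouped margins)
  for ρ; moments of the non-censored values for μ, σ; marginal
  inverse-normal quantiles for τ.

Thresholds for grouped margins are *sampled jointly* with ρ by default
(one-step). A two-step mode (`thresholds="fixed"`) pins them at the
marginal quantiles as a cross-check; the two agree within Monte-Carlo
error in the tests.

Missing data are handled by pairwise deletion and the pairwise n is
reported with every estimate — correlation tables in this field
conventionally report per-pair n.

## Psychometric corrections

Classical test theory, closed-form:

* Cronbach's α = k/(k−1) · (1 − Σ item variances / variance of sum).
* Spearman–Brown: R = k r / (1 + (k−1) r), and its exact inverse
  r = R / (k − (k−1) R), used to back-calculate single-component
  reliability from a k-year composite.
* Two-part composite reliability: Spearman–Brown at k = 2 applied to the
  mean of the two part reliabilities (the only two-number formula
  consistent with the conventional usage).
* Disattenuation: r_xy / √(r_xx r_yy). Values above 1 in magnitude are
  reported as computed, with a warning — not clipped.
* Two-sample power: normal approximation with noncentrality
  d·√(n₁n₂/(n₁+n₂)). The `tails` argument is explicit because the
  directional and non-directional versions differ materially; the
  package default for the reproduction scenario is one-sided.

## Path model

Variables carry a declared causal (temporal) order. Each variable from
the second onward is regressed on all prior variables; predictors with
the largest p ≥ 0.05 are removed one at a time (never re-entering; ties
broken by removing the later-ordered column first, deterministically)
and the model refitted until all survivors are significant. Coefficients
are standardized β (both sides z-scored), so retained edges are path
weights. Listwise deletion is used per target regression — per-pair
deletion is incoherent for multiple regression. Ordinal outcomes enter
regressions as numeric category scores. The graph is acyclic by
construction and exported as DOT with pen-width proportional to |β|.

## Synthetic cohorts

The generator emulates the data structure the estimators are built for,
with the generating truth retained:

* **Simplex latent structure** — stage scores are multivariate normal
  with corr(i, k) = product of the lag-1 correlations between i and k
  (the signature of a stage-wise causal chain), or any supplied
  positive-definite matrix.
* **Selection** — deterministic top-fraction truncation on a stage score
  (default; the cleanest restriction-of-range testbed) or logistic
  probabilistic selection.
* **Observation** — per stage: Gaussian measurement noise parameterised
  by reliability (default 0.8-0.9, consistent with typical examination
  reliabilities); ceiling censoring at an empirical quantile (so a
  declared ceiling mass such as 62.5% holds in the generated sample);
  ordinal grouping at cumulative-proportion quantiles; or a binary
  threshold at a stated prevalence.
* **Uptake** — attempt probability for a later exam is logistic in an
  earlier latent score; non-attempters' later values are set missing and
  the attempt flag kept. Preset intercepts are calibrated by quadrature
  (Gauss–Legendre over the truncated selection score × Gauss–Hermite
  over the independent component, inverted by bisection) so the marginal
  uptake matches the preset's stated fraction among entrants.

Two presets ship: a modern-cohort preset (729 entrants, 62.5% A-level
ceiling mass, 34.6% post-graduate uptake rising with undergraduate
attainment at logistic slope 0.75 — slope chosen to give an
attempter/non-attempter separation of roughly 0.4 SD) and a
selection-era preset (applicant pool with 48.3% entering, a 4-category
ordinal pre-clinical outcome with proportions 6.7/28.3/53.3/11.7% from
fail to distinction, and a binary specialist-register end state at 55.4%
prevalence).

All randomness flows from the single config seed through
`numpy.random.SeedSequence` spawns; identical configs give byte-identical
output bundles.

### What the generator does and does not emulate

It reproduces the *statistical* structure — simplex correlations,
restriction of range, ceiling mass, ordinal margins, outcome-dependent
missingness. It does not attempt demographic realism beyond optional
binary-covariate mean shifts, discrete grade-point support (grades are
continuous-with-ceiling by default, which is the appropriate testbed for
the censored-correlation estimator), cohort effects over calendar time,
or non-normal latent distributions. Passing recovery tests therefore
shows the estimators are correct *under the latent-normal model*, not
that real grade data satisfy that model.

## Numerical choices and problem sizes

* ρ is kept inside (−1, 1) by machine tolerance; zero-probability cells
  return −∞ rather than raising, so the sampler simply rejects.
* Degenerate inputs fail loudly: fewer than 10 pairwise-complete pairs,
  single-valued margins, zero-spread z-score groups, mixed
  O-level/GCSE takers.
* Estimator validation uses n = 1000–5000 per dataset, 100 replicates
  for coverage, 50 replicates for path-model recovery, and n = 10⁵ for
  generator mass checks — sizes at which Monte-Carlo error is small
  relative to the tolerances being asserted while a full validation run
  remains a desk-scale computation.
* The minimum pairwise n for a reported matrix cell is 10
  (configurable).

## Known limitations

* The estimator is pairwise: no joint >2-variable latent-normal fit, so
  the corrected correlation matrix is not guaranteed positive definite.
* Percentile intervals from a single chain can under-cover slightly when
  the chain mixes slowly (very heavy censoring, tiny n); chain length
  10000 is the documented remedy.
* Construct-validity correction of entrant correlations back to the
  applicant pool (restriction-of-range correction proper) is out of
  scope; the generator produces the phenomenon, the estimator does not
  undo it.
* The power routine is the normal approximation, not the noncentral-t.
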