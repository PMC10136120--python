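# Methods

## Study design being modelled

Adult females of a predatory mite and its spider-mite prey are held singly
on leaf arenas under a repeating diurnal heat-wave programme — *mild*
(T_max 32.0 °C) or *extreme* (T_max 38.0 °C), twelve 2-hour
temperature/humidity steps, 16:8 L:D — for 10 days, crossed with juvenile
acclimation (matching vs non-matching juvenile thermal environment).
Daily records are the female's state (alive / dead / escaped), eggs laid
and food consumption; up to two eggs per ovipositing female per day are
measured (volume) and reared to determine sex.  Because females eclose
over one day, age at the first daily assessment is taken as t = 3.5 days
and 12.5 days at the last.  The two regime profiles are stored as data
constants; the extreme profile is the mild one plus exactly 6 °C at every
step, and table means are displayed with one-decimal round-half-up.

## Competing fates

Escape and death are competing daily-resolution fates.  The escape
function is the product-limit estimator with deaths censored at their
fate day and day-10 survivors censored at 10; the survival function
follows the study's convention of conditioning on never-escapers
(restriction is the default; escape-censoring is available via
`death_mode="censor"`).  Ties: all events at a day share the risk set,
and censoring at a day follows the events.

The Breslow (Gehan, generalised Wilcoxon) test weights each event time by
the total number at risk.  It is implemented through Gehan scores
s_j = (#subjects j demonstrably outlives) − (#subjects that demonstrably
outlive j); the group statistic is the score sum and its covariance is
the *exact label-permutation* covariance

V_gh = [Σ s_j² / (N(N−1))] · (N·n_g·δ_gh − n_g·n_h),

with a chi-square on k−1 groups.  This choice makes the variance exactly
testable against an exhaustive permutation reference (the tests do this
on 8-subject data) while remaining numerically close to the risk-set
hypergeometric variant used by common survival software (the suite
cross-checks against lifelines' Wilcoxon-weighted log-rank).  The
chi-square p-value is asymptotic; on very small samples it can differ
from the exact permutation p by up to ~0.1, which the tests document.

## The age-dependent rate curve

All rates and egg volumes share y(t) = a·t^b·e^(ct+dt²), a > 0.  b > 0
forces y(0) = 0 (appropriate for oviposition), c < 0 produces a
gamma-shaped curve peaking where 2dt² + ct + b = 0 (−b/c when d = 0);
egg-volume fits drop b and keep the quadratic term, and are expressed in
10⁶ µm³.

Two estimation routes:

- **NLS** (`fit_nls`): Levenberg–Marquardt least squares on the original
  scale, parameterised in ln a so the scale stays positive, started from
  an ordinary log-linear fit of ln(y+1); tolerances 1e-12.  R² is
  1 − SSE/SST over the observed responses.  When a cluster column is
  supplied (female id), standard errors use a cluster-robust sandwich
  (J'J bread, per-female score meat), reflecting that each female
  contributes all her daily observations; otherwise classical
  σ²(J'J)⁻¹ SEs are reported.  Observations are pooled across
  female-days (no per-female weighting).
- **Log-linear GEE-style** (`fit_loglinear`): OLS of
  ln y = β₀ + β₁ ln t + β₂ t + β₃ t² + factor effects with a sandwich
  covariance clustered on female — working-independence estimating
  equations, which give Wald-type between-subject tests without
  positing a working correlation.  The +1 offset before the log applies
  to oviposition and consumption only, never to egg volumes.  Factors
  use sum-to-zero coding; per-term Wald chi-squares follow the Type-III
  convention; backward elimination removes the largest-p term with
  p > 0.05, never removing a term contained in a retained interaction,
  and records the trace.

The two routes agree exactly on noiseless volume data (no offset), and on
rate data their point estimates differ systematically because
E[ln(y+1)] ≠ ln(E y + 1); both are exposed because each matches one of
the original analysis tools.

## Ratio-of-means inference

m = a/b with SE(m) = m·√((SE_a/a)² + (SE_b/b)²) (first-order delta
method, independent groups), 95 % t limits on a_n+b_n−2 df.  Two ratios
are compared with t = (m₁−m₂)/√(SE₁²+SE₂²).  The default df is the sum
of the four group sizes minus 4; published tables whose printed dfs
follow no reconstructable rule are reproduced by passing the printed df
explicitly.  A parametric bootstrap (normal resampling of both means)
validates the delta SE to within 5 % relative error whenever the
denominator CV is below 0.1; no Fieller interval is provided.

## Factorial GLMs

`fit_factorial` covers the normal (identity), Poisson (log) and binomial
(logit) families, always scaling the covariance by the Pearson χ²/df
dispersion — for the normal family this equals the residual mean square,
so the normal fit reproduces textbook two-way ANOVA F statistics on
balanced data (verified against a hand-computed sums-of-squares oracle).
Per-term tests are scaled Wald F with the residual df; elimination is as
above, interaction first.  Sex ratios are analysed per female (number of
female eggs of n sexed over the 10 days; females surviving the full
period), as a quasi-binomial fit with the trials as variance weights.

Post-hoc contrasts are pairwise level differences on the link scale,
averaged over the other factors' levels (exact marginal means under
sum-to-zero coding).  The normal family uses the exact studentized-range
(Tukey) distribution; the quasi families use Holm-adjusted scaled-Wald t
tests, labelled as Tukey/Dunnett analogues — exact multivariate-t
adjustments are deliberately out of scope, since the decisions (which
pairs differ) are the quantity of interest.

## Synthetic cohorts

`simulate_cohort` draws, for each female and day, in this fixed order:
fate (escape hazard first, then death), egg count, consumption, then the
sexing subsample.  Components:

- **Hazards.**  Constant daily escape/death probabilities per cell.
  `calibrate_hazards` inverts the 10-day competing-risk recursion in
  closed form so that expected fate fractions match the reported cell
  decompositions (e.g. 36/47 escaped, 5/47 died for non-acclimated
  predators under extreme heat waves; the cells sum to the reported
  134/188 predator and 20/181 prey escapes).
- **Egg counts.**  Negative binomial with mean μ from the oviposition
  curve and variance φμ (φ = `count_dispersion`, default 2; Poisson at
  φ = 1), times a female-level lognormal frailty multiplier (unit mean,
  log-SD 0.2 by default).  The frailty induces the within-female
  correlation that the clustered inference assumes; its magnitude is a
  free design parameter, not an estimate, since day-to-day correlations
  were not reported.
- **Egg volumes.**  Lognormal around the per-sex, per-regime age curve
  with CV 0.05 by default (chosen small because the published volume
  fits have R² ≈ 0.99); sex is Bernoulli in the regime's female
  fraction.  Predator egg axes are reconstructed from the volume with a
  fixed elongation a/b = 1.3 (typical for prolate mite eggs); prey eggs
  are spheres.
- **Consumption.**  Predator: negative binomial around the published
  predation-rate curve.  Prey: truncated-normal daily leaf damage with
  the published means and an SD back-computed from the reported SE at
  the analysis size (~54 females/cell).
- Escaped/dead females contribute eggs only on days strictly before the
  fate day; the fate-day row records the terminal status with missing
  egg/consumption values.

`default_configs` fixes the eight cells at the published cell sizes
(42–54 females), curve estimates and sex ratios.  What the generator does
*not* emulate: within-day thermal dynamics, behavioural responses to
predator cues, age- or regime-dependent hazards (they are constant per
cell), and any correlation between a female's fecundity and her
escape/death risk.  Passing tests therefore show that the estimators
recover the generating process under the study's design and noise
levels — not that the original biological data satisfy these
assumptions.

## Problem sizes and numerical conventions

Simulation-based checks use cohorts of 200 females per cell with 100
replicates for parameter recovery, 1000 null replicates at 40 females per
group for Breslow calibration, 5000 females for the closed-form
Kaplan–Meier comparison, and 10⁵ bootstrap draws for the delta-method
check; these sizes give Monte-Carlo errors comfortably below the
tolerances being asserted.  All simulations are reproducible from a
single integer seed; the pipeline's outputs are byte-identical under a
fixed seed.  Degenerate inputs (all-zero responses, single observed age,
empty factor cells, complete separation in the sex-ratio fit, zero
events in survival tests) are rejected with explicit errors rather than
silently fitted.  The curve scale a = 0 is admitted only as the null
curve used to represent "no oviposition" in simulations; fitted scales
are always positive by construction.
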