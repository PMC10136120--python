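# heatmite

Statistical analysis of a predator–prey heat-wave reproduction experiment:
the predatory mite *Phytoseiulus persimilis* and its prey, the two-spotted
spider mite *Tetranychus urticae*, observed daily for 10 days on bean-leaf
arenas under mild (T_max = 32 °C) or extreme (T_max = 38 °C) diurnal
heat-wave regimes, with or without juvenile acclimation.  The package is
aimed at quantitative ecologists who want to re-run this style of
life-history analysis on their own long-format female-day data, or to
study its statistical behaviour on simulated cohorts.

## What it computes

- **Fates and escape/survival functions.**  Each female ends the window
  *survived*, *died* or *escaped* (competing fates at daily resolution).
  Escape functions are product-limit estimates f(t) with f(0) = 1, deaths
  censored; survival is estimated among never-escapers.  Homogeneity
  between groups is tested with the Gehan–Breslow generalised Wilcoxon
  test (risk-set-weighted log-rank scores with the exact permutation
  variance).
- **Age-dependent rate curves.**  Oviposition rate, predation rate and
  egg volume are modelled by one generic curve of maternal age *t*:

  y(t) = a·t^b·e^(ct + dt²)

  fitted by nonlinear least squares on the original scale and, in
  log-linear form ln y = β₀ + β₁ ln t + β₂ t + β₃ t² (+ treatment
  factors), by working-independence estimating equations with a sandwich
  covariance clustered on female — a GEE-style repeated-measures
  analysis.  For rates, 1 is added before taking logs.  With b > 0 and
  c < 0 the curve is gamma-shaped with an interior peak at −b/c.
- **Ratio-of-means heat-wave effects.**  m = a/b of mean daily rates
  under extreme vs mild regimes, with first-order delta-method SE and
  95 % limits, a t test between two ratios, and percent changes
  100·(a−b)/b.
- **Factorial GLMs.**  Two-way ANOVA for feeding damage;
  overdispersion-scaled Poisson GLM for oviposition under predation
  risk; overdispersion-scaled binomial GLM for offspring sex ratios —
  all with sum-to-zero (Type-III-style) term tests, stepwise backward
  elimination at p > 0.05, and Tukey / control-vs-others post-hoc
  contrasts.
- **Egg morphometrics.**  Volumes from V = (4/3)π a b² (prolate
  predator eggs) or V = (4/3)π r³ (spherical prey eggs), and the
  two-eggs-per-female-day sexing subsample rule.
- **Synthetic cohorts.**  An individual-based generator reproduces the
  study design (daily escape/death hazards, negative-binomial egg
  counts around the age curve, female-level frailty, lognormal egg-size
  noise, regime-dependent sex ratios), parameterised by the published
  estimates, so every analysis stage is testable without the deposited
  raw data.

## Worked example

```python
import heatmite as hm

# heat-wave effect on daily oviposition, from the published rate summaries
r_pred = hm.ratio_of_means(3.199, 0.115, 93, 1.788, 0.111, 86)
r_prey = hm.ratio_of_means(10.889, 0.667, 79, 8.696, 0.275, 101)
comp = hm.compare_ratios(r_pred, r_prey, df=362)

# peak of the predator's oviposition curve under extreme heat waves
from heatmite._reference import OVIPOSITION_PARAMS
p = OVIPOSITION_PARAMS[("predator", "extreme")]

# a full synthetic study and its fate analysis
females, eggs = hm.simulate_cells(seed=1)
fates = hm.female_fates(females)
tallies = hm.tally_fates(fates, ["species"])
res = hm.breslow_from_fates(fates, "species", "escape")
```

prints (via the obvious f-strings):

```
predator extreme:mild ratio = 1.789 +/- 0.128
prey     extreme:mild ratio = 1.252 +/- 0.086
difference: t = 3.472, p = 0.0006
predator extreme oviposition peaks at 5.82 d (3.75 eggs/female/day)
predator: 188 females, 70.21% escaped, 20.74% survived
prey: 181 females, 9.39% escaped, 60.77% survived
escape functions differ between species: chi2 = 133.4, p = 7.3e-31
```

The ratios say extreme heat waves raise the predator's egg-laying rate by
~79 % but the prey's by only ~25 %, and that those two relative responses
differ (t = 3.47).  The simulated cohort reproduces the experiment's
headline asymmetry: about 70 % of predator females leave the leaf within
10 days versus about 10 % of prey females.

A command-line pipeline wraps the same stages:

```sh
heatmite report --seed 42 --out run1     # simulate -> fates -> curves -> ratios -> glm -> report
heatmite validate --females run1/females.csv --eggs run1/eggs.csv
```

## Layout

- `src/heatmite/heatwave_profiles.py` — the two diurnal regimes
- `src/heatmite/synthetic_cohort.py` — individual-based cohort generator
- `src/heatmite/fate_analysis.py` — tallies, product-limit curves, Breslow test
- `src/heatmite/rate_curves.py` — the age-dependent curve, NLS and GEE-style fits
- `src/heatmite/ratio_stats.py` — delta-method ratio inference
- `src/heatmite/factorial_glm.py` — ANOVA / quasi-Poisson / quasi-binomial fits
- `src/heatmite/morphometrics.py` — egg geometry and sexing subsample
- `src/heatmite/pipeline.py`, `cli.py` — orchestration and the `heatmite` CLI
- `docs/methods.md` — models, assumptions and design choices
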