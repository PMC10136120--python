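"""Published summary values from the original heat-wave reproduction study.

These printed estimates (figure-caption curve parameters, cell-level fate
counts, rate summaries, sexed-egg counts) are *inputs*: they parameterise
the synthetic cohort generator and serve as worked-example fixtures that
the reports juxtapose with freshly computed statistics.  Raw individual
data are not bundled.
"""

from __future__ import annotations

from .rate_curves import RateCurveParams

# --- age-dependent oviposition-rate parameters (per species x regime,
#     pooled over acclimation); y(t) in eggs/female/day, d dropped -------------
OVIPOSITION_PARAMS = {
    ("predator", "extreme"): RateCurveParams(
        a=0.8970, b=1.8765, c=-0.3223,
        se={"a": 0.2893, "b": 0.4005, "c": 0.0643},
        included_terms=frozenset("bc"), response_kind="oviposition",
    ),
    ("predator", "mild"): RateCurveParams(
        a=0.1683, b=2.9610, c=-0.4390,
        se={"a": 0.0651, "b": 0.4409, "c": 0.0665},
        included_terms=frozenset("bc"), response_kind="oviposition",
    ),
    ("prey", "extreme"): RateCurveParams(
        a=1.4600, b=2.3705, c=-0.3230,
        se={"a": 0.4371, "b": 0.3158, "c": 0.0441},
        included_terms=frozenset("bc"), response_kind="oviposition",
    ),
    ("prey", "mild"): RateCurveParams(
        a=0.5416, b=2.8919, c=-0.3723,
        se={"a": 0.1124, "b": 0.2117, "c": 0.0288},
        included_terms=frozenset("bc"), response_kind="oviposition",
    ),
}

# --- predation-rate parameters of the predator (prey eggs eaten/day);
#     b and d dropped: the rate declines monotonically with age --------------
PREDATION_PARAMS = {
    "extreme": RateCurveParams(
        a=38.0805, c=-0.0505, se={"a": 1.5148, "c": 0.0065},
        included_terms=frozenset("c"), response_kind="predation",
    ),
    "mild": RateCurveParams(
        a=25.9780, c=-0.0387, se={"a": 1.0046, "c": 0.0058},
        included_terms=frozenset("c"), response_kind="predation",
    ),
}

# --- egg-volume parameters (units of 1e6 um^3; b dropped, quadratic age
#     term retained), per species x regime x egg sex, pooled over acclimation -
EGG_VOLUME_PARAMS = {
    ("predator", "extreme", "female"): RateCurveParams(
        a=4.0776, c=-0.0116, d=0.00095, se={"a": 0.1523, "c": 0.0124, "d": 0.00091},
        included_terms=frozenset("cd"), response_kind="egg_volume", r_squared=0.992,
    ),
    ("predator", "mild", "female"): RateCurveParams(
        a=3.6088, c=0.0436, d=-0.00028, se={"a": 0.1406, "c": 0.0121, "d": 0.00085},
        included_terms=frozenset("cd"), response_kind="egg_volume", r_squared=0.992,
    ),
    ("predator", "extreme", "male"): RateCurveParams(
        a=3.7318, c=-0.0334, d=0.00033, se={"a": 0.1816, "c": 0.0168, "d": 0.00012},
        included_terms=frozenset("cd"), response_kind="egg_volume", r_squared=0.989,
    ),
    ("predator", "mild", "male"): RateCurveParams(
        a=3.5284, c=0.0220, d=-0.0010, se={"a": 0.2198, "c": 0.0204, "d": 0.0015},
        included_terms=frozenset("cd"), response_kind="egg_volume", r_squared=0.989,
    ),
    ("prey", "extreme", "female"): RateCurveParams(
        a=1.0148, c=0.0425, d=-0.0020, se={"a": 0.0352, "c": 0.0105, "d": 0.00072},
        included_terms=frozenset("cd"), response_kind="egg_volume", r_squared=0.991,
    ),
    ("prey", "mild", "female"): RateCurveParams(
        a=0.9490, c=0.0747, d=-0.0044, se={"a": 0.0225, "c": 0.0068, "d": 0.00045},
        included_terms=frozenset("cd"), response_kind="egg_volume", r_squared=0.993,
    ),
    ("prey", "extreme", "male"): RateCurveParams(
        a=0.9194, c=0.0633, d=-0.0035, se={"a": 0.0309, "c": 0.0099, "d": 0.00066},
        included_terms=frozenset("cd"), response_kind="egg_volume", r_squared=0.992,
    ),
    ("prey", "mild", "male"): RateCurveParams(
        a=0.9722, c=0.0559, d=-0.0028, se={"a": 0.0345, "c": 0.0103, "d": 0.00067},
        included_terms=frozenset("cd"), response_kind="egg_volume", r_squared=0.990,
    ),
}

# --- 10-day fate decomposition per treatment cell, reconstructed from the
#     reported cell sizes, escape comparisons and survival-of-non-escapers
#     comparisons (cells sum to 134/188 predator and 20/181 prey escapes,
#     40 and 108 survivors) ---------------------------------------------------
FATE_CELLS = {
    # (species, acclimated, regime): dict(n, escaped, died)
    ("predator", False, "mild"): {"n": 42, "escaped": 23, "died": 2},
    ("predator", False, "extreme"): {"n": 47, "escaped": 36, "died": 5},
    ("predator", True, "mild"): {"n": 54, "escaped": 43, "died": 3},
    ("predator", True, "extreme"): {"n": 45, "escaped": 32, "died": 4},
    ("prey", False, "mild"): {"n": 48, "escaped": 10, "died": 9},
    ("prey", False, "extreme"): {"n": 39, "escaped": 1, "died": 15},
    ("prey", True, "mild"): {"n": 52, "escaped": 8, "died": 11},
    ("prey", True, "extreme"): {"n": 42, "escaped": 1, "died": 18},
}

# --- mean daily oviposition rates (mean, SE, n) per species x regime,
#     censored = day-10 survivors only, uncensored = all females --------------
OVIPOSITION_RATE_SUMMARY = {
    ("predator", "uncensored", "extreme"): (3.199, 0.115, 93),
    ("predator", "uncensored", "mild"): (1.788, 0.111, 86),
    ("prey", "uncensored", "extreme"): (10.889, 0.667, 79),
    ("prey", "uncensored", "mild"): (8.696, 0.275, 101),
    ("predator", "censored", "extreme"): (3.11, 0.274, 15),
    ("predator", "censored", "mild"): (2.12, 0.180, 25),
    ("prey", "censored", "extreme"): (13.957, 0.619, 46),
    ("prey", "censored", "mild"): (9.824, 0.183, 62),
}

#: printed degrees of freedom of the published between-ratio tests (they do
#: not follow the sum-of-ns-minus-4 rule; kept for fixture reproduction)
RATIO_TEST_DF = {"uncensored": 362, "censored": 154}

# --- sexed-egg tallies and per-regime proportions of female eggs -------------
SEXED_EGGS = {
    "predator": {"n_female": 496, "n_sexed": 762, "p_female": {"mild": 0.692, "extreme": 0.618}},
    "prey": {"n_female": 1126, "n_sexed": 1927, "p_female": {"mild": 0.631, "extreme": 0.506}},
}

# --- prey leaf-damage rates, mm^2/female/day (mean, SE) per regime -----------
PREY_FEEDING = {"extreme": (14.79, 0.96), "mild": (11.70, 0.43)}

# --- predation-risk experiment, eggs/female over 2 days (mean, SE) -----------
RISK_EXPERIMENT_OVIPOSITION = {"extreme": (13.28, 0.14), "mild": (5.67, 0.10)}
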