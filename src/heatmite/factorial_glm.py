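"""Factorial analyses of female-level summaries.

Three analyses share one fitting surface:

* two-way ANOVA of feeding damage (normal family, identity link);
* oviposition under heat waves x predation risk (Poisson family, log
  link, covariance scaled by the Pearson chi^2/df dispersion);
* offspring sex ratios (binomial family, logit link, same scaling).

Factors enter with sum-to-zero coding so per-term Wald tests mirror the
Type-III convention; non-significant terms (p > 0.05) are removed
stepwise, interactions before the main effects they contain.  For the
quasi families the dispersion estimate multiplies the covariance, which
guards the type-I error against extra-Poisson/binomial variation.

Post-hoc contrasts are pairwise level differences on the link scale:
exact Tukey studentized-range adjustment for the normal family, and
Holm-adjusted scaled-Wald tests (a Tukey/Dunnett analogue) for the quasi
families, including a control-versus-others mode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rate_curves import _term_factors

__all__ = [
    "GlmResult",
    "fit_factorial",
    "posthoc_contrasts",
    "sex_ratio_analysis",
]

FAMILIES = {
    "normal": (sm.families.Gaussian, "identity"),
    "quasi_poisson": (sm.families.Poisson, "log"),
    "quasi_binomial": (sm.families.Binomial, "logit"),
}


@dataclass
class GlmResult:
    family: str
    link: str
    formula: str
    params: pd.Series
    bse: pd.Series
    dispersion: float
    term_tests: pd.DataFrame  # term, chi_square, df, F, p, retained
    elimination_trace: list
    factors: tuple
    result: object = None
    data: pd.DataFrame = None
    pooled: pd.DataFrame | None = None


def _glm_wald_terms(res, design_info) -> pd.DataFrame:
    """Scaled Wald chi-square and F per term (covariance already scaled)."""
    rows = []
    cov = np.asarray(res.cov_params())
    beta = np.asarray(res.params)
    df_resid = res.df_resid
    for term in design_info.terms:
        name = term.name()
        if name == "Intercept":
            continue
        sl = design_info.term_name_slices[name]
        idx = list(range(*sl.indices(len(beta))))
        if not idx:  # single-level factor: vacuous term
            continue
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        F = chi2 / df
        rows.append(
            {
                "term": name,
                "chi_square": chi2,
                "df": df,
                "F": F,
                "p": float(stats.f.sf(F, df, df_resid)),
            }
        )
    return pd.DataFrame(rows)


def _fit_glm(formula, data, family_name, var_weights=None):
    fam_cls, _ = FAMILIES[family_name]
    model = smf.glm(formula, data=data, family=fam_cls(), var_weights=var_weights)
    exog = model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError(
            "singular design (empty cells produce aliased terms); "
            f"rank {np.linalg.matrix_rank(exog)} < {exog.shape[1]} columns"
        )
    res = model.fit(scale="X2")
    if not np.all(np.isfinite(np.asarray(res.params))):
        raise RuntimeError("IRLS did not converge to finite coefficients")
    return res


def fit_factorial(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, ...],
    family: str = "normal",
    *,
    trials: str | None = None,
    eliminate: bool = True,
    alpha: float = 0.05,
) -> GlmResult:
    """Factorial GLM with Pearson-dispersion scaling and Type-III term tests.

    For ``family='quasi_binomial'`` the response column must hold the
    per-female proportion and ``trials`` the denominator column.

    The full model crosses all factors; backward elimination removes the
    term with the largest p > alpha first, keeping main effects while any
    interaction containing them is retained.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {tuple(FAMILIES)}")
    if family == "quasi_binomial" and trials is None:
        raise ValueError("quasi_binomial requires the trials column")
    data = table.copy()
    weights = data[trials].astype(float) if trials else None
    coded = {f: f"C({f}, Sum)" for f in factors}
    terms = ["*".join(coded[f] for f in factors)] if len(factors) > 1 else [coded[factors[0]]]
    # expand the patsy '*' shorthand into explicit terms so we can eliminate
    full = []
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            full.append(":".join(coded[f] for f in combo))
    current = full
    trace: list = []
    while True:
        formula = f"{response} ~ " + (" + ".join(current) if current else "1")
        res = _fit_glm(formula, data, family, var_weights=weights)
        design_info = res.model.data.design_info
        tests = _glm_wald_terms(res, design_info)
        if not eliminate or tests.empty:
            break
        tf = _term_factors(design_info)
        removable = [
            n for n in tests["term"]
            if not any(tf[n] < tf[m] for m in tests["term"] if m != n)
        ]
        cand = tests[tests["term"].isin(removable) & (tests["p"] > alpha)]
        if cand.empty:
            break
        worst = cand.sort_values("p", ascending=False).iloc[0]
        trace.append((worst["term"], float(worst["chi_square"]), float(worst["p"])))
        current = [t for t in current if t != worst["term"]]

    tests["retained"] = True
    dropped = pd.DataFrame(
        [
            {"term": t, "chi_square": x, "df": np.nan, "F": np.nan, "p": p, "retained": False}
            for t, x, p in trace
        ]
    )
    tests = pd.concat([tests, dropped], ignore_index=True) if len(dropped) else tests
    _, link = FAMILIES[family]
    return GlmResult(
        family=family,
        link=link,
        formula=formula,
        params=res.params,
        bse=res.bse,
        dispersion=float(res.scale),
        term_tests=tests,
        elimination_trace=trace,
        factors=tuple(factors),
        result=res,
        data=data,
    )


def _emm_rows(fit: GlmResult, factor: str) -> tuple[list, np.ndarray]:
    """Design-matrix rows for each level of `factor`, averaged over the
    other factors' levels (equal weights; exact marginal means under the
    sum-to-zero coding)."""
    from patsy import dmatrix

    design_info = fit.result.model.data.design_info
    levels = {f: sorted(fit.data[f].unique()) for f in fit.factors}
    if factor not in levels:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    grid = pd.DataFrame(
        list(itertools.product(*levels.values())), columns=list(levels.keys())
    )
    X = np.asarray(dmatrix(design_info, grid))
    target = sorted(levels[factor])
    rows = np.stack([X[(grid[factor] == lev).to_numpy()].mean(axis=0) for lev in target])
    return target, rows


def posthoc_contrasts(
    fit: GlmResult,
    factor: str,
    adjustment: str = "tukey",
    control: object | None = None,
) -> pd.DataFrame:
    """Pairwise (or control-vs-others) level contrasts on the link scale.

    'tukey' uses the exact studentized-range distribution for the normal
    family and Holm-adjusted scaled-Wald t tests otherwise;
    'dunnett_style' compares the control level (default: first sorted
    level) against the others with Holm adjustment; 'holm' is all-pairs
    with Holm adjustment.
    """
    levels, rows = _emm_rows(fit, factor)
    if len(levels) < 2:
        raise ValueError("factor needs at least two observed levels")
    cov = np.asarray(fit.result.cov_params())
    beta = np.asarray(fit.result.params)
    df_resid = fit.result.df_resid
    k = len(levels)

    if adjustment == "dunnett_style":
        ctrl = control if control is not None else levels[0]
        if ctrl not in levels:
            raise ValueError(f"control level {ctrl!r} not found")
        pairs = [(ctrl, lev) for lev in levels if lev != ctrl]
    else:
        pairs = list(itertools.combinations(levels, 2))

    recs = []
    for l1, l2 in pairs:
        L = rows[levels.index(l1)] - rows[levels.index(l2)]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        tstat = est / se
        if adjustment == "tukey" and fit.family == "normal":
            q = abs(tstat) * np.sqrt(2.0)
            p_raw = float(stats.studentized_range.sf(q, k, df_resid))
            p_adj = p_raw  # the studentized-range p is already family-wise
        else:
            p_raw = float(2.0 * stats.t.sf(abs(tstat), df_resid))
            p_adj = np.nan  # filled below by Holm
        recs.append(
            {"level_1": l1, "level_2": l2, "estimate": est, "se": se, "t": tstat,
             "p_raw": p_raw, "p_adj": p_adj}
        )
    out = pd.DataFrame(recs)
    if out["p_adj"].isna().any():
        out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method="holm")[1]
    out["p_adj"] = np.maximum(out["p_adj"], out["p_raw"])
    out["adjustment"] = adjustment
    return out


def sex_ratio_analysis(
    eggs: pd.DataFrame,
    factors: tuple[str, ...] = ("regime", "acclimated"),
    *,
    eliminate: bool = True,
) -> GlmResult:
    """Quasi-binomial logistic regression of the per-female proportion of
    female eggs (10-day totals) on the treatment factors.

    Only sexed eggs enter; each female contributes one binomial
    observation (n_female successes of n sexed).  The returned result
    carries pooled female proportions per factor level in ``.pooled``.
    """
    sexed = eggs[eggs["sex"].isin(["female", "male"])]
    if sexed.empty:
        raise ValueError("no sexed eggs to analyse")
    per_female = (
        sexed.assign(is_female=(sexed["sex"] == "female").astype(float))
        .groupby(["female_id", *factors], sort=True, observed=True)
        .agg(n_female=("is_female", "sum"), n=("is_female", "size"))
        .reset_index()
    )
    per_female["prop_female"] = per_female["n_female"] / per_female["n"]
    boundary = per_female["prop_female"].isin([0.0, 1.0]).all()
    fit = None
    if boundary:
        raise ValueError(
            "all per-female proportions are at the boundary (0 or 1); "
            "the logistic fit is degenerate (complete separation)"
        )
    fit = fit_factorial(
        per_female,
        "prop_female",
        factors,
        family="quasi_binomial",
        trials="n",
        eliminate=eliminate,
    )
    pooled_rows = [
        {
            "level": "overall",
            "factor": "",
            "n_female": per_female["n_female"].sum(),
            "n": per_female["n"].sum(),
            "pct_female": 100.0 * per_female["n_female"].sum() / per_female["n"].sum(),
        }
    ]
    for f in factors:
        for lev, grp in per_female.groupby(f, sort=True):
            pooled_rows.append(
                {
                    "level": lev,
                    "factor": f,
                    "n_female": grp["n_female"].sum(),
                    "n": grp["n"].sum(),
                    "pct_female": 100.0 * grp["n_female"].sum() / grp["n"].sum(),
                }
            )
    fit.pooled = pd.DataFrame(pooled_rows)
    return fit
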