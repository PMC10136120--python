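"""Age-dependent rate and egg-volume curves.

A single generic model describes daily oviposition rates, predation rates
and egg volumes as a function of maternal age ``t`` (days since adult
eclosion)::

    y(t) = a * t**b * exp(c*t + d*t**2)

with scale ``a > 0`` and shape parameters ``b`` (power), ``c`` (linear
exponent) and ``d`` (quadratic exponent).  With ``b > 0`` the curve is
zero at t = 0 and, for ``c < 0``, gamma-shaped with an interior peak at
``-b/c`` (d = 0) — the classic age-specific fecundity form.  Egg-volume
fits drop the power term (b = 0) and use the quadratic exponent instead.

Two fitting routes are provided:

* :func:`fit_nls` — nonlinear least squares on the original scale
  (optionally with a cluster-robust sandwich covariance over females);
* :func:`fit_loglinear` — the log-linearisation
  ``ln y = b0 + b1 ln t + b2 t + b3 t^2 + factor effects``, estimated by
  working-independence estimating equations (OLS point estimates with a
  sandwich covariance clustered on female), i.e. a GEE-style repeated
  measures analysis.  For oviposition and consumption rates one is added
  to the response before taking logs; never for egg volumes.

Backward elimination removes terms with p > 0.05 stepwise, largest p
first, respecting marginality (a main effect is never removed while an
interaction containing it is retained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import optimize, stats

__all__ = [
    "RateCurveParams",
    "LogLinearFit",
    "eval_curve",
    "peak_age",
    "fit_nls",
    "fit_loglinear",
]

RESPONSE_KINDS = ("oviposition", "predation", "egg_volume")
#: response kinds whose log-linearisation uses ln(y + 1)
PLUS_ONE_KINDS = ("oviposition", "predation")


@dataclass(frozen=True)
class RateCurveParams:
    """Parameters of y(t) = a t^b exp(ct + dt^2) for one stratum.

    Dropped terms are exactly zero and carry no standard error.
    """

    a: float
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    se: Mapping[str, float] = field(default_factory=dict)
    included_terms: frozenset = frozenset(("b", "c"))
    r_squared: float | None = None
    response_kind: str = "oviposition"
    converged: bool = True
    n_obs: int | None = None

    def __post_init__(self) -> None:
        # a = 0 is allowed only as the degenerate null curve (y identically 0)
        if self.a < 0:
            raise ValueError("scale parameter a must be nonnegative")
        for name in ("b", "c", "d"):
            if name not in self.included_terms and getattr(self, name) != 0.0:
                raise ValueError(f"dropped term {name} must be exactly 0")


def eval_curve(params: RateCurveParams, t):
    """Evaluate y(t) = a t^b exp(ct + dt^2) at age(s) t (days).

    Egg-volume parameter sets are in the scaled units of the source fits
    (1e6 um^3); multiply by 1e6 for um^3.
    """
    t = np.asarray(t, dtype=float)
    if params.b != 0.0 and np.any(t <= 0):
        raise ValueError("age t must be positive when the power term is present")
    out = params.a * np.where(params.b != 0.0, np.power(np.where(t > 0, t, 1.0), params.b), 1.0)
    out = out * np.exp(params.c * t + params.d * t * t)
    return out if out.ndim else float(out)


def peak_age(params: RateCurveParams) -> float | None:
    """Age of the interior maximum of the curve, or None if monotone.

    Stationary points solve b/t + c + 2 d t = 0, i.e. 2 d t^2 + c t + b = 0
    on t > 0 (closed form -b/c when d = 0).
    """
    b, c, d = params.b, params.c, params.d
    if d == 0.0:
        if b > 0 and c < 0:
            return -b / c
        return None
    disc = c * c - 8.0 * d * b
    if disc < 0:
        return None
    roots = [(-c + s * np.sqrt(disc)) / (4.0 * d) for s in (+1.0, -1.0)]
    for t in sorted(r for r in roots if r > 0):
        # maximum where the log-derivative crosses from + to -: g'(t) < 0
        if -b / t**2 + 2.0 * d < 0:
            return float(t)
    return None


# ---------------------------------------------------------------------------
# log-linear (GEE-style) fitting
# ---------------------------------------------------------------------------

_AGE_TERMS = {"b": "np.log(age)", "c": "age", "d": "I(age ** 2)"}
_TERM_TO_PARAM = {"Intercept": "a", "np.log(age)": "b", "age": "c", "I(age ** 2)": "d"}


@dataclass
class LogLinearFit:
    """Result of the log-linear repeated-measures fit."""

    formula: str
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    term_tests: pd.DataFrame  # term, chi_square, df, p, retained
    elimination_trace: list
    offset_plus_one: bool
    response_kind: str
    n_obs: int
    n_clusters: int
    result: object = None  # statsmodels results for the final model

    @property
    def implied_params(self) -> RateCurveParams:
        """Back-transform the age terms to the original-scale curve."""
        get = lambda k: float(self.params.get(k, 0.0))
        included = frozenset(
            p for t, p in _TERM_TO_PARAM.items() if t != "Intercept" and t in self.params.index
        )
        return RateCurveParams(
            a=float(np.exp(get("Intercept"))),
            b=get("np.log(age)"),
            c=get("age"),
            d=get("I(age ** 2)"),
            included_terms=included,
            response_kind=self.response_kind,
        )


def _term_factors(design_info) -> dict[str, frozenset]:
    return {
        t.name(): frozenset(f.name() for f in t.factors)
        for t in design_info.terms
        if t.name() != "Intercept"
    }


def _wald_terms(res, design_info) -> pd.DataFrame:
    """Per-term Wald chi-square tests on the (robust) covariance."""
    rows = []
    cov = res.cov_params()
    beta = res.params
    for term in design_info.terms:
        name = term.name()
        if name == "Intercept":
            continue
        sl = design_info.term_name_slices[name]
        idx = list(range(*sl.indices(len(beta))))
        if not idx:  # single-level factor: vacuous term
            continue
        b = np.asarray(beta)[idx]
        V = np.asarray(cov)[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        rows.append({"term": name, "chi_square": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))})
    return pd.DataFrame(rows)


def _fit_ols_clustered(formula: str, data: pd.DataFrame, groups: pd.Series | None):
    model = smf.ols(formula, data=data)
    if groups is not None and groups.nunique() > 1:
        return model.fit(cov_type="cluster", cov_kwds={"groups": groups}, use_t=False)
    return model.fit()


def fit_loglinear(
    table: pd.DataFrame,
    response: str,
    response_kind: str = "oviposition",
    *,
    age_col: str = "age",
    cluster: str | None = "female_id",
    included_terms: Sequence[str] = ("b", "c", "d"),
    factors: Sequence[str] = (),
    interactions: Sequence[tuple[str, ...]] = (),
    eliminate: bool = True,
    alpha: float = 0.05,
) -> LogLinearFit:
    """Fit the log-linearised age model with cluster-robust inference.

    Parameters
    ----------
    table : long female-day (or egg) table with one row per observation.
    response : response column on the original scale (counts or volumes).
    factors : treatment factors entered with sum-to-zero coding.
    interactions : tuples of term labels (factor names or 'b'/'c'/'d' age
        terms) crossed into the model, e.g. ``[("regime", "c")]``.
    eliminate : stepwise-remove terms with p > alpha (largest first),
        never removing a term contained in a retained interaction.
    """
    if response_kind not in RESPONSE_KINDS:
        raise ValueError(f"unknown response_kind {response_kind!r}")
    offset_plus_one = response_kind in PLUS_ONE_KINDS

    data = table.copy()
    y = data[response].astype(float)
    if offset_plus_one:
        if (y < 0).any():
            raise ValueError("rates must be nonnegative")
        data["_lny"] = np.log1p(y)
    else:
        if (y <= 0).any():
            raise ValueError("volumes must be positive for the log transform")
        data["_lny"] = np.log(y)
    if (data[age_col] <= 0).any():
        raise ValueError("ages must be positive")
    data = data.rename(columns={age_col: "age"}) if age_col != "age" else data
    if data["_lny"].nunique() == 1 and data["_lny"].iloc[0] == 0.0:
        raise ValueError("degenerate fit: all responses are zero")

    def tlabel(x: str) -> str:
        return _AGE_TERMS[x] if x in _AGE_TERMS else f"C({x}, Sum)"

    terms = [tlabel(x) for x in included_terms] + [tlabel(f) for f in factors]
    terms += [":".join(tlabel(x) for x in inter) for inter in interactions]
    groups = data[cluster] if cluster else None

    trace: list = []
    current = list(terms)
    while True:
        formula = "_lny ~ " + (" + ".join(current) if current else "1")
        res = _fit_ols_clustered(formula, data, groups)
        design_info = res.model.data.design_info
        tests = _wald_terms(res, design_info)
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
        # drop the term from the working list (match on rebuilt label)
        current = [t for t in current if t != worst["term"]]
        if len(current) == len(terms):  # pragma: no cover - label mismatch guard
            raise RuntimeError(f"could not remove term {worst['term']!r}")
        terms = list(current)

    tests["retained"] = True
    tests = pd.concat(
        [tests]
        + [
            pd.DataFrame(
                [{"term": t, "chi_square": x, "df": np.nan, "p": p, "retained": False}]
            )
            for t, x, p in trace
        ],
        ignore_index=True,
    )
    return LogLinearFit(
        formula=formula,
        params=res.params,
        bse=res.bse,
        cov=res.cov_params(),
        term_tests=tests,
        elimination_trace=trace,
        offset_plus_one=offset_plus_one,
        response_kind=response_kind,
        n_obs=int(res.nobs),
        n_clusters=int(groups.nunique()) if groups is not None else int(res.nobs),
        result=res,
    )


# ---------------------------------------------------------------------------
# nonlinear least squares on the original scale
# ---------------------------------------------------------------------------


def _nls_single(
    t: np.ndarray,
    y: np.ndarray,
    included: tuple[str, ...],
    response_kind: str,
    clusters: np.ndarray | None,
) -> RateCurveParams:
    n_par = 1 + len(included)
    if len(np.unique(t)) < n_par + 1:
        raise ValueError("too few distinct ages to identify the curve parameters")
    if np.any(y < 0):
        raise ValueError("responses must be nonnegative")

    # start values from the crude log-linear fit of ln(y + 1)
    X_cols = {"b": np.log(t), "c": t, "d": t * t}
    X = np.column_stack([np.ones_like(t)] + [X_cols[k] for k in included])
    beta0, *_ = np.linalg.lstsq(X, np.log1p(y), rcond=None)
    theta0 = np.array(beta0, dtype=float)  # [ln a, included shape params]

    def predict(theta):
        ln = theta[0] + sum(th * X_cols[k] for th, k in zip(theta[1:], included))
        return np.exp(ln)

    # model in terms of ln a (keeps a positive); shape params unconstrained
    def resid(theta):
        return predict(theta) - y

    sol = optimize.least_squares(resid, theta0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    theta = sol.x
    converged = bool(sol.success)
    if not converged:
        warnings.warn("nonlinear fit did not converge; returning best iterate", RuntimeWarning)

    r = sol.fun
    J = sol.jac
    sse = float(r @ r)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    dof = max(len(y) - n_par, 1)
    JtJ = J.T @ J
    try:
        bread = np.linalg.inv(JtJ)
        if clusters is None:
            cov = sse / dof * bread
        else:
            meat = np.zeros_like(JtJ)
            for g in np.unique(clusters):
                m = clusters == g
                s = J[m].T @ r[m]
                meat += np.outer(s, s)
            cov = bread @ meat @ bread
        se_theta = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_theta = np.full(n_par, np.nan)

    a = float(np.exp(theta[0]))
    se = {"a": a * float(se_theta[0])}  # delta method for a = exp(ln a)
    vals = {"b": 0.0, "c": 0.0, "d": 0.0}
    for i, k in enumerate(included):
        vals[k] = float(theta[1 + i])
        se[k] = float(se_theta[1 + i])
    return RateCurveParams(
        a=a,
        b=vals["b"],
        c=vals["c"],
        d=vals["d"],
        se=se,
        included_terms=frozenset(included),
        r_squared=r2,
        response_kind=response_kind,
        converged=converged,
        n_obs=len(y),
    )


def fit_nls(
    table: pd.DataFrame,
    response: str,
    response_kind: str = "oviposition",
    *,
    age_col: str = "age",
    included_terms: Sequence[str] = ("b", "c"),
    strata: Sequence[str] | None = None,
    cluster: str | None = None,
):
    """Least-squares fit of y(t) = a t^b exp(ct + dt^2) on the original scale.

    R^2 is 1 - SSE/SST over the observed responses.  When `cluster`
    names a column (e.g. ``female_id``), standard errors use a sandwich
    covariance clustered on it, matching the repeated-measures design in
    which the same females contribute all their daily observations.

    Returns a single :class:`RateCurveParams`, or a dict keyed by stratum
    when ``strata`` is given.
    """
    included = tuple(k for k in ("b", "c", "d") if k in included_terms)

    def one(df: pd.DataFrame) -> RateCurveParams:
        t = df[age_col].to_numpy(dtype=float)
        y = df[response].to_numpy(dtype=float)
        cl = df[cluster].to_numpy() if cluster else None
        if np.any(t <= 0):
            raise ValueError("ages must be positive")
        return _nls_single(t, y, included, response_kind, cl)

    if strata is None:
        return one(table)
    out = {}
    for key, grp in table.groupby(list(strata), sort=True):
        out[key if len(strata) > 1 else key[0] if isinstance(key, tuple) else key] = one(grp)
    return out
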