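"""Fates, escape/survival step functions, and the Breslow test.

Each female ends the 10-day observation window in one of three states:
*survived* (still alive on the leaf on the final day), *died* (found dead
on the leaf) or *escaped* (left the leaf).  Escape and death are competing
fates resolved at daily resolution.

The escape function f(t) is the product-limit (Kaplan-Meier) estimate of
the probability of still residing on the leaf at day t, with deaths
censored at their fate day.  The survival function is, by the study's
convention, estimated among the never-escaping females (restriction mode,
the default); escape-censoring is exposed as an alternative.

Group homogeneity is tested with the Gehan-Breslow generalised Wilcoxon
test: the weighted log-rank statistic with weights equal to the number at
risk, here computed through Gehan scores with the exact permutation
covariance, so the statistic is directly testable against an exhaustive
label-permutation reference.  All same-day events share the risk set and
censoring at a time follows the events at that time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FateTally",
    "KMFunction",
    "BreslowResult",
    "female_fates",
    "tally_fates",
    "product_limit",
    "km_curve",
    "gehan_scores",
    "breslow_test",
    "breslow_from_fates",
]

FATES = ("survived", "died", "escaped")
ENDPOINTS = ("escape", "death", "loss")


@dataclass(frozen=True)
class FateTally:
    group: tuple
    n_total: int
    n_escaped: int
    n_died: int
    n_survived: int

    def percentage(self, fate: str) -> float | None:
        if self.n_total == 0:
            return None
        return 100.0 * getattr(self, f"n_{fate}") / self.n_total


@dataclass(frozen=True)
class KMFunction:
    """Product-limit step function; f(0) = 1 by construction."""

    endpoint: str
    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    estimate: np.ndarray

    def at(self, t) -> np.ndarray | float:
        """Step-function value(s) at time(s) t."""
        t = np.asarray(t, dtype=float)
        if len(self.event_times) == 0:
            vals = np.ones_like(t)
            return vals if vals.ndim else float(vals)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        vals = np.where(idx >= 0, self.estimate[np.clip(idx, 0, None)], 1.0)
        return vals if vals.ndim else float(vals)


@dataclass(frozen=True)
class BreslowResult:
    chi_square: float
    df: int
    p_value: float
    group_labels: tuple
    statistic_by_group: Mapping


def female_fates(females: pd.DataFrame, n_days: int | None = None) -> pd.DataFrame:
    """Collapse a long female-day table to one row per female with her fate.

    The table must carry ``female_id``, ``day`` and ``status`` columns
    (status in {'alive', 'died', 'escaped'}); treatment labels present in
    the table are carried through.  ``duration`` is the fate day for
    events and the final observation day for survivors.
    """
    carry = [c for c in ("species", "acclimated", "regime") if c in females.columns]
    last = (
        females.sort_values(["female_id", "day"])
        .groupby("female_id", sort=True)
        .tail(1)
        .set_index("female_id")
    )
    horizon = n_days if n_days is not None else int(females["day"].max())
    fate = last["status"].map({"alive": "survived", "died": "died", "escaped": "escaped"})
    if fate.isna().any():
        bad = last["status"][fate.isna()].unique()
        raise ValueError(f"unknown status values: {list(bad)}")
    out = pd.DataFrame(
        {
            "fate": fate,
            "fate_day": last["day"].where(fate != "survived"),
            "duration": last["day"].where(fate != "survived", horizon).astype(float),
        }
    )
    for c in carry:
        out[c] = last[c]
    return out.reset_index()


def tally_fates(fates: pd.DataFrame, group_by: Sequence[str] = ()) -> list[FateTally]:
    """Per-group fate counts; percentages recompute from the counts.

    Accepts either a per-female fate table (from :func:`female_fates`) or
    any frame with a ``fate`` column.
    """
    group_by = list(group_by)
    if not group_by:
        groups = [((), fates)]
    else:
        groups = [
            (key if isinstance(key, tuple) else (key,), grp)
            for key, grp in fates.groupby(group_by, sort=True)
        ]
    out = []
    for key, grp in groups:
        counts = grp["fate"].value_counts()
        out.append(
            FateTally(
                group=key,
                n_total=int(len(grp)),
                n_escaped=int(counts.get("escaped", 0)),
                n_died=int(counts.get("died", 0)),
                n_survived=int(counts.get("survived", 0)),
            )
        )
    return out


def tally_frame(tallies: Sequence[FateTally], group_names: Sequence[str] = ()) -> pd.DataFrame:
    rows = []
    for t in tallies:
        row = dict(zip(group_names, t.group))
        row.update(
            n_total=t.n_total,
            n_escaped=t.n_escaped,
            n_died=t.n_died,
            n_survived=t.n_survived,
            pct_escaped=t.percentage("escaped"),
            pct_died=t.percentage("died"),
            pct_survived=t.percentage("survived"),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def product_limit(durations, events, endpoint: str = "escape") -> KMFunction:
    """Product-limit estimate from (duration, event) pairs.

    Ties: all events at a time share the risk set; censoring at the same
    time occurs after the events.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValueError("at least one record is required")
    order = np.argsort(durations, kind="stable")
    durations, events = durations[order], events[order]
    times = np.unique(durations[events])
    n = len(durations)
    at_risk = np.empty(len(times), dtype=int)
    d = np.empty(len(times), dtype=int)
    est = np.empty(len(times), dtype=float)
    surv = 1.0
    for i, t in enumerate(times):
        at_risk[i] = int(np.sum(durations >= t))
        d[i] = int(np.sum((durations == t) & events))
        surv *= 1.0 - d[i] / at_risk[i]
        est[i] = surv
    return KMFunction(endpoint=endpoint, event_times=times, n_at_risk=at_risk, n_events=d, estimate=est)


def _durations_events(fates: pd.DataFrame, endpoint: str, n_days: int, death_mode: str):
    if endpoint == "escape":
        dur = fates["duration"].to_numpy(dtype=float)
        ev = (fates["fate"] == "escaped").to_numpy()
        return dur, ev
    if endpoint == "loss":  # escaped or died, the pooled total-loss endpoint
        dur = fates["duration"].to_numpy(dtype=float)
        ev = (fates["fate"] != "survived").to_numpy()
        return dur, ev
    if endpoint == "death":
        if death_mode == "restrict":
            sub = fates[fates["fate"] != "escaped"]
            if sub.empty:
                raise ValueError("no never-escaping females to estimate death from")
            return sub["duration"].to_numpy(dtype=float), (sub["fate"] == "died").to_numpy()
        if death_mode == "censor":
            return fates["duration"].to_numpy(dtype=float), (fates["fate"] == "died").to_numpy()
        raise ValueError("death_mode must be 'restrict' or 'censor'")
    raise ValueError(f"endpoint must be one of {ENDPOINTS}")


def km_curve(
    fates: pd.DataFrame,
    endpoint: str = "escape",
    *,
    n_days: int = 10,
    death_mode: str = "restrict",
) -> KMFunction:
    """Escape or survival step function from a per-female fate table.

    For ``endpoint='death'`` the default follows the study's conditioning
    on never-escapers (``death_mode='restrict'``); ``'censor'`` keeps
    escapers in the risk set until their escape day.
    """
    dur, ev = _durations_events(fates, endpoint, n_days, death_mode)
    return product_limit(dur, ev, endpoint=endpoint)


# ---------------------------------------------------------------------------
# Gehan-Breslow generalised Wilcoxon test
# ---------------------------------------------------------------------------


def gehan_scores(durations, events) -> np.ndarray:
    """Gehan score of each subject: (#definitely outlived) - (#definitely outlived by).

    Subject j definitely outlives subject k when k's event was observed
    and either t_j > t_k, or t_j == t_k with j censored.
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    tj = t[:, None]
    tk = t[None, :]
    beats = (e[None, :]) & ((tj > tk) | ((tj == tk) & ~e[:, None]))
    return beats.sum(axis=1) - beats.sum(axis=0)


def breslow_test(groups: Mapping[object, tuple]) -> BreslowResult:
    """Gehan-Breslow test for homogeneity of escape/survival functions.

    Parameters
    ----------
    groups : mapping label -> (durations, events) for two or more groups.

    The statistic is the Gehan score sum per group with the exact
    label-permutation covariance; the chi-square uses a generalised
    inverse on k-1 groups with df = k-1.
    """
    labels = tuple(groups.keys())
    if len(labels) < 2:
        raise ValueError("at least two groups are required")
    durs, evs, gidx = [], [], []
    for i, lab in enumerate(labels):
        d, e = groups[lab]
        d = np.asarray(d, dtype=float)
        e = np.asarray(e, dtype=bool)
        durs.append(d)
        evs.append(e)
        gidx.append(np.full(len(d), i))
    t = np.concatenate(durs)
    e = np.concatenate(evs)
    g = np.concatenate(gidx)
    if not e.any():
        raise ValueError("no events in any group; the statistic is undefined")
    s = gehan_scores(t, e)
    N = len(t)
    ng = np.array([np.sum(g == i) for i in range(len(labels))], dtype=float)
    U = np.array([s[g == i].sum() for i in range(len(labels))], dtype=float)
    s2 = float(np.sum(s.astype(float) ** 2))
    # exact permutation covariance of the group score sums
    V = (s2 / (N * (N - 1))) * (N * np.diag(ng) - np.outer(ng, ng))
    k = len(labels)
    Vr = V[: k - 1, : k - 1]
    Ur = U[: k - 1]
    if s2 == 0:
        raise ValueError("zero score variance; the statistic is undefined")
    chi2 = float(Ur @ np.linalg.solve(Vr, Ur))
    chi2 = max(chi2, 0.0)
    df = k - 1
    return BreslowResult(
        chi_square=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        group_labels=labels,
        statistic_by_group=dict(zip(labels, U)),
    )


def breslow_from_fates(
    fates: pd.DataFrame,
    group_by: str,
    endpoint: str = "escape",
    *,
    n_days: int = 10,
    death_mode: str = "restrict",
) -> BreslowResult:
    """Convenience wrapper: group a fate table and run the Breslow test."""
    groups = {}
    for key, grp in fates.groupby(group_by, sort=True):
        groups[key] = _durations_events(grp, endpoint, n_days, death_mode)
    return breslow_test(groups)
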