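"""End-to-end orchestration: simulate -> fates -> curves -> ratios -> glm -> report.

Each stage reads/writes flat CSV files in the run's output directory, so
a run is a pure function of (inputs, config, seed).  All randomness flows
through one seeded generator.  The report juxtaposes freshly computed
statistics with the published worked-example values bundled as fixtures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _reference as ref
from . import factorial_glm, fate_analysis, rate_curves, ratio_stats
from .heatwave_profiles import display_round, make_profile, profile_mean, write_profiles_csv
from .synthetic_cohort import default_configs, simulate_cells

__all__ = ["RunConfig", "run_pipeline", "validate_tables", "load_config", "STAGES"]

STAGES = ("simulate", "fates", "curves", "ratios", "glm", "report")

FEMALES_COLUMNS = (
    "female_id", "species", "acclimated", "regime", "day", "age", "status", "eggs", "consumption",
)
EGGS_COLUMNS = (
    "female_id", "species", "acclimated", "regime", "day", "maternal_age",
    "shape", "a_um", "b_um", "r_um", "volume_um3", "sex",
)


@dataclass
class RunConfig:
    out_dir: str | Path = "heatmite_run"
    seed: int | None = None
    stages: tuple[str, ...] = STAGES
    females_path: str | Path | None = None  # analyse user data instead of simulating
    eggs_path: str | Path | None = None
    n_days: int = 10

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("at least one stage must be requested")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid stages: {STAGES}")
        order = [s for s in STAGES if s in self.stages]
        self.stages = tuple(order)
        if "simulate" in self.stages and self.females_path is None and self.seed is None:
            raise ValueError("a seed is mandatory when simulating")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing required column(s): {', '.join(missing)}")


def _female_rates(females: pd.DataFrame) -> pd.DataFrame:
    """Per-female mean daily oviposition rate over her observed alive days."""
    alive = females[females["status"] == "alive"]
    agg = (
        alive.groupby(["female_id", "species", "acclimated", "regime"], sort=True)
        .agg(total_eggs=("eggs", "sum"), alive_days=("eggs", "size"),
             mean_consumption=("consumption", "mean"))
        .reset_index()
    )
    agg["rate"] = agg["total_eggs"] / agg["alive_days"]
    return agg


def _stage_fates(females, out: Path, files: dict) -> dict:
    fates = fate_analysis.female_fates(females)
    tallies = fate_analysis.tally_frame(
        fate_analysis.tally_fates(fates, ["species"]), ["species"]
    )
    cell = fate_analysis.tally_frame(
        fate_analysis.tally_fates(fates, ["species", "acclimated", "regime"]),
        ["species", "acclimated", "regime"],
    )
    tallies = pd.concat([tallies, cell], ignore_index=True)

    km_rows, test_rows = [], []
    for endpoint in ("escape", "death"):
        for (species, regime), grp in fates.groupby(["species", "regime"], sort=True):
            try:
                km = fate_analysis.km_curve(grp, endpoint)
            except ValueError:
                continue
            for t, n, d, f in zip(km.event_times, km.n_at_risk, km.n_events, km.estimate):
                km_rows.append(
                    {"species": species, "regime": regime, "endpoint": endpoint,
                     "time": t, "at_risk": n, "events": d, "estimate": f}
                )
    for endpoint in ("loss", "escape", "death"):
        try:
            res = fate_analysis.breslow_from_fates(fates, "species", endpoint)
            test_rows.append(
                {"comparison": f"species ({endpoint})", "chi_square": res.chi_square,
                 "df": res.df, "p": res.p_value}
            )
        except ValueError:
            pass
        for species, grp in fates.groupby("species", sort=True):
            try:
                res = fate_analysis.breslow_from_fates(grp, "regime", endpoint)
                test_rows.append(
                    {"comparison": f"{species}: regime ({endpoint})",
                     "chi_square": res.chi_square, "df": res.df, "p": res.p_value}
                )
            except ValueError:
                pass

    tallies.to_csv(out / "fate_tallies.csv", index=False)
    pd.DataFrame(km_rows).to_csv(out / "km_curves.csv", index=False)
    pd.DataFrame(test_rows).to_csv(out / "tests.csv", index=False)
    files.update(fate_tallies="fate_tallies.csv", km_curves="km_curves.csv", tests="tests.csv")
    return {"fates": fates, "tallies": tallies}


def _stage_curves(females, out: Path, files: dict) -> dict:
    fates = fate_analysis.female_fates(females)
    survivors = set(fates.loc[fates["fate"] == "survived", "female_id"])
    alive = females[(females["status"] == "alive") & females["female_id"].isin(survivors)]
    fit_rows, gee_rows = [], []
    fits = {}
    for (species, regime), grp in alive.groupby(["species", "regime"], sort=True):
        params = rate_curves.fit_nls(
            grp, "eggs", "oviposition", included_terms=("b", "c"), cluster="female_id"
        )
        fits[(species, regime)] = params
        for name in ("a", "b", "c"):
            fit_rows.append(
                {"species": species, "regime": regime, "response": "oviposition",
                 "parameter": name, "estimate": getattr(params, name),
                 "se": params.se.get(name, np.nan), "r_squared": params.r_squared}
            )
    for species, grp in alive.groupby("species", sort=True):
        gee = rate_curves.fit_loglinear(
            grp, "eggs", "oviposition",
            factors=("regime", "acclimated"),
            interactions=(("regime", "c"),),
        )
        for _, row in gee.term_tests.iterrows():
            gee_rows.append(
                {"species": species, "term": row["term"], "chi_square": row["chi_square"],
                 "df": row["df"], "p": row["p"], "retained": row["retained"]}
            )
    pd.DataFrame(fit_rows).to_csv(out / "curve_fits.csv", index=False)
    pd.DataFrame(gee_rows).to_csv(out / "gee_tests.csv", index=False)
    files.update(curve_fits="curve_fits.csv", gee_tests="gee_tests.csv")
    return {"nls_fits": fits}


def _summary_ratio(summ, species, mode):
    ae, se_e, ne = summ[(species, mode, "extreme")]
    am, se_m, nm = summ[(species, mode, "mild")]
    return ratio_stats.ratio_of_means(ae, se_e, ne, am, se_m, nm, censoring_mode=mode)


def ratios_from_summary(summary: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ratio report from a summary table (species, mode, regime, mean, se, n).

    Each (species, mode) pair with both regimes present yields one
    extreme:mild ratio; modes with both species yield a between-ratio test.
    """
    _require_columns(summary, ("species", "mode", "regime", "mean", "se", "n"), "summary table")
    table = {
        (r.species, r.mode, r.regime): (float(r.mean), float(r.se), int(r.n))
        for r in summary.itertuples()
    }
    rows, comp_rows = [], []
    for mode in sorted({k[1] for k in table}):
        pair = {}
        for species in sorted({k[0] for k in table}):
            if (species, mode, "extreme") not in table or (species, mode, "mild") not in table:
                continue
            r = _summary_ratio(table, species, mode)
            pair[species] = r
            rows.append(
                {"mode": mode, "species": species, "ratio": r.ratio, "se": r.se,
                 "ci_low": r.ci_low, "ci_high": r.ci_high,
                 "percent_change": ratio_stats.percent_change(r.a_mean, r.b_mean)}
            )
        if len(pair) == 2:
            s1, s2 = sorted(pair)
            comp = ratio_stats.compare_ratios(pair[s1], pair[s2])
            comp_rows.append(
                {"mode": mode, "comparison": f"{s1} vs {s2}",
                 "difference": comp.difference, "se": comp.se, "t": comp.t,
                 "df": comp.df, "p": comp.p}
            )
    return pd.DataFrame(rows), pd.DataFrame(comp_rows)


def _stage_ratios(females, out: Path, files: dict) -> dict:
    rates = _female_rates(females)
    fates = fate_analysis.female_fates(females)
    survivors = set(fates.loc[fates["fate"] == "survived", "female_id"])

    summ = {}
    for (species, regime), grp in rates.groupby(["species", "regime"], sort=True):
        for mode, sub in (
            ("uncensored", grp),
            ("censored", grp[grp["female_id"].isin(survivors)]),
        ):
            if len(sub) < 2:
                continue
            x = sub["rate"].to_numpy()
            summ[(species, mode, regime)] = (
                float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x))), len(x)
            )

    rows, comp_rows = [], []
    for source, table in (("simulated", summ), ("reference", ref.OVIPOSITION_RATE_SUMMARY)):
        for mode in ("uncensored", "censored"):
            pair = {}
            for species in ("predator", "prey"):
                if (species, mode, "extreme") not in table or (species, mode, "mild") not in table:
                    continue
                r = _summary_ratio(table, species, mode)
                pair[species] = r
                rows.append(
                    {"source": source, "mode": mode, "species": species,
                     "ratio": r.ratio, "se": r.se, "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "percent_change": ratio_stats.percent_change(r.a_mean, r.b_mean)}
                )
            if len(pair) == 2:
                df = ref.RATIO_TEST_DF[mode] if source == "reference" else None
                comp = ratio_stats.compare_ratios(pair["predator"], pair["prey"], df=df)
                comp_rows.append(
                    {"source": source, "mode": mode,
                     "comparison": "predator vs prey extreme:mild ratio",
                     "difference": comp.difference, "se": comp.se, "t": comp.t,
                     "df": comp.df, "p": comp.p}
                )
    ratios = pd.DataFrame(rows)
    comparisons = pd.DataFrame(comp_rows)
    ratios.to_csv(out / "ratios.csv", index=False)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    files.update(ratios="ratios.csv", comparisons="comparisons.csv")
    return {"ratios": ratios, "comparisons": comparisons}


def _stage_glm(females, eggs, out: Path, files: dict) -> dict:
    fates = fate_analysis.female_fates(females)
    survivors = set(fates.loc[fates["fate"] == "survived", "female_id"])
    glm_rows = []
    results = {}
    for species, grp in eggs.groupby("species", sort=True):
        sub = grp[grp["female_id"].isin(survivors)]
        if sub.empty:
            continue
        try:
            fit = factorial_glm.sex_ratio_analysis(sub)
        except ValueError:
            continue
        results[f"sex_ratio_{species}"] = fit
        for _, row in fit.term_tests.iterrows():
            glm_rows.append(
                {"analysis": f"sex_ratio_{species}", "family": fit.family, "term": row["term"],
                 "chi_square": row["chi_square"], "F": row.get("F", np.nan),
                 "df": row["df"], "p": row["p"], "retained": row["retained"],
                 "dispersion": fit.dispersion}
            )
        for _, row in fit.pooled.iterrows():
            glm_rows.append(
                {"analysis": f"sex_ratio_{species}", "family": "pooled",
                 "term": f"pct_female[{row['factor']}={row['level']}]",
                 "chi_square": np.nan, "F": np.nan, "df": row["n"],
                 "p": row["pct_female"] / 100.0, "retained": True,
                 "dispersion": np.nan}
            )
    # prey feeding two-way ANOVA on per-female mean damage (survivors only)
    rates = _female_rates(females)
    prey = rates[(rates["species"] == "prey") & rates["female_id"].isin(survivors)]
    if prey["mean_consumption"].notna().sum() > 8:
        fit = factorial_glm.fit_factorial(
            prey.dropna(subset=["mean_consumption"]),
            "mean_consumption", ("regime", "acclimated"), family="normal",
        )
        results["prey_feeding"] = fit
        for _, row in fit.term_tests.iterrows():
            glm_rows.append(
                {"analysis": "prey_feeding", "family": fit.family, "term": row["term"],
                 "chi_square": row["chi_square"], "F": row.get("F", np.nan),
                 "df": row["df"], "p": row["p"], "retained": row["retained"],
                 "dispersion": fit.dispersion}
            )
    pd.DataFrame(glm_rows).to_csv(out / "glm_results.csv", index=False)
    files.update(glm_results="glm_results.csv")
    return {"glm": results}


def _stage_report(state: dict, config: RunConfig, out: Path, files: dict) -> None:
    buf = io.StringIO()
    w = buf.write
    w("heatmite pipeline report\n")
    w(f"seed: {config.seed}\n")
    w(f"stages: {', '.join(config.stages)}\n\n")

    w("Diurnal regimes (24-h means):\n")
    for regime in ("mild", "extreme"):
        p = make_profile(regime)
        w(
            f"  {regime}: {display_round(profile_mean(p, 'temperature'))} C, "
            f"{display_round(profile_mean(p, 'humidity'))} % RH\n"
        )
    w("\n")

    if "tallies" in state:
        w("Fate tallies (computed | reference where applicable):\n")
        t = state["tallies"]
        pooled = t[t.get("acclimated").isna()] if "acclimated" in t else t
        for _, row in pooled.iterrows():
            refpct = "71.28" if row["species"] == "predator" else "11.05"
            w(
                f"  {row['species']}: escaped {row['pct_escaped']:.2f} % "
                f"(reference {refpct} %), survived {row['pct_survived']:.2f} %\n"
            )
        w("\n")

    if "ratios" in state:
        w("Extreme:mild oviposition-rate ratios (ratio +/- SE):\n")
        for _, row in state["ratios"].iterrows():
            w(
                f"  [{row['source']}] {row['species']} ({row['mode']}): "
                f"{row['ratio']:.3f} +/- {row['se']:.3f} "
                f"({row['percent_change']:.2f} % change)\n"
            )
        for _, row in state["comparisons"].iterrows():
            w(
                f"  [{row['source']}] {row['comparison']} ({row['mode']}): "
                f"t_{row['df']:.0f} = {row['t']:.3f}, p = {row['p']:.4f}\n"
            )
        w("\n")

    if "nls_fits" in state:
        w("Fitted oviposition curves y(t) = a t^b exp(ct) [reference in brackets]:\n")
        for (species, regime), p in sorted(state["nls_fits"].items()):
            r = ref.OVIPOSITION_PARAMS[(species, regime)]
            w(
                f"  {species}/{regime}: a={p.a:.4f} [{r.a}], b={p.b:.4f} [{r.b}], "
                f"c={p.c:.4f} [{r.c}], R^2={p.r_squared:.3f}\n"
            )
        w("\n")

    w("Reference sexed-egg proportions: predator 65.1 % female (496/762), "
      "prey 58.4 % female (1126/1927)\n")
    (out / "report.txt").write_text(buf.getvalue())
    files.update(report="report.txt")


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages; returns a dict of in-memory results and
    the paths of everything written."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict = {}
    state: dict = {}

    if config.females_path is not None:
        females = pd.read_csv(config.females_path)
        _require_columns(females, FEMALES_COLUMNS, str(config.females_path))
        eggs = pd.read_csv(config.eggs_path) if config.eggs_path else pd.DataFrame(columns=EGGS_COLUMNS)
    elif "simulate" in config.stages or set(config.stages) - {"report"}:
        females, eggs = simulate_cells(seed=config.seed)
    else:
        females = eggs = None

    for stage in config.stages:
        try:
            if stage == "simulate":
                females.to_csv(out / "females.csv", index=False)
                eggs.to_csv(out / "eggs.csv", index=False)
                write_profiles_csv(out / "profiles.csv")
                files.update(females="females.csv", eggs="eggs.csv", profiles="profiles.csv")
            elif stage == "fates":
                state.update(_stage_fates(females, out, files))
            elif stage == "curves":
                state.update(_stage_curves(females, out, files))
            elif stage == "ratios":
                state.update(_stage_ratios(females, out, files))
            elif stage == "glm":
                state.update(_stage_glm(females, eggs, out, files))
            elif stage == "report":
                _stage_report(state, config, out, files)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    state["files"] = {k: str(out / v) for k, v in files.items()}
    return state


# ---------------------------------------------------------------------------
# table validation
# ---------------------------------------------------------------------------


def validate_tables(
    females_path=None, eggs_path=None
) -> pd.DataFrame:
    """Schema and invariant checks on interchange CSVs.

    Returns one row per file with pass/fail, row counts and the violations
    found (absorbing-state breaches, negative counts, geometry conflicts,
    eggs recorded after a female's fate day).
    """
    rows = []
    females = None
    if females_path is not None:
        problems = []
        try:
            females = pd.read_csv(females_path)
        except OSError as exc:
            raise OSError(f"cannot read {females_path}: {exc}") from exc
        missing = [c for c in FEMALES_COLUMNS if c not in females.columns]
        if missing:
            problems.append(f"missing columns: {', '.join(missing)}")
        else:
            if (females["eggs"].dropna() < 0).any():
                problems.append("negative egg counts")
            bad_status = set(females["status"].unique()) - {"alive", "died", "escaped"}
            if bad_status:
                problems.append(f"unknown status values: {sorted(bad_status)}")
            for fid, grp in females.sort_values("day").groupby("female_id"):
                st = grp["status"].tolist()
                ev = [i for i, s in enumerate(st) if s in ("died", "escaped")]
                if ev and ev[0] != len(st) - 1:
                    problems.append(f"female {fid}: records after terminal status")
                    break
                if ev and not grp["eggs"].iloc[ev[0] :].isna().all():
                    problems.append(f"female {fid}: eggs recorded on/after fate day")
                    break
        rows.append(
            {"file": str(females_path), "n_rows": 0 if females is None else len(females),
             "passed": not problems, "problems": "; ".join(problems)}
        )
    if eggs_path is not None:
        problems = []
        try:
            eggs = pd.read_csv(eggs_path)
        except OSError as exc:
            raise OSError(f"cannot read {eggs_path}: {exc}") from exc
        missing = [c for c in EGGS_COLUMNS if c not in eggs.columns]
        if missing:
            problems.append(f"missing columns: {', '.join(missing)}")
        else:
            if (eggs["volume_um3"] <= 0).any():
                problems.append("nonpositive egg volumes")
            sphere = eggs["shape"] == "sphere"
            both = (eggs["r_um"].notna() & (eggs["a_um"].notna() | eggs["b_um"].notna()))
            if both.any():
                problems.append("rows with both spherical and ellipsoidal axes")
            if (sphere & eggs["r_um"].isna()).any() or (~sphere & eggs["a_um"].isna()).any():
                problems.append("shape does not match the populated axes")
            if females is not None and not females.empty:
                fates = fate_analysis.female_fates(females)
                ev = fates[fates["fate"] != "survived"].set_index("female_id")["fate_day"]
                merged = eggs.join(ev, on="female_id")
                if (merged["day"] >= merged["fate_day"]).fillna(False).any():
                    problems.append("egg observations on/after a female's fate day")
        rows.append(
            {"file": str(eggs_path), "n_rows": len(eggs),
             "passed": not problems, "problems": "; ".join(problems)}
        )
    return pd.DataFrame(rows)
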