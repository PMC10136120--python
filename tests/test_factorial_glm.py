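import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import logit

from heatmite.factorial_glm import fit_factorial, posthoc_contrasts, sex_ratio_analysis


def balanced_two_way(rng=None, n_per_cell=20, effects=(1.5, -0.8, 0.0), noise=0.0):
    """Balanced 2x2 layout: mu + A + B (+ optional AB) with sum-to-zero effects."""
    a_eff, b_eff, ab_eff = effects
    rows = []
    for ai, a in enumerate(("a0", "a1")):
        for bi, b in enumerate(("b0", "b1")):
            sa = 1 if ai else -1
            sb = 1 if bi else -1
            mu = 10.0 + sa * a_eff + sb * b_eff + sa * sb * ab_eff
            for _ in range(n_per_cell):
                y = mu + (rng.normal(0, noise) if noise else 0.0)
                rows.append({"A": a, "B": b, "y": y})
    return pd.DataFrame(rows)


class TestFitFactorial:
    def test_noiseless_balanced_layout_recovered_exactly(self):
        df = balanced_two_way(effects=(1.5, -0.8, 0.4))
        fit = fit_factorial(df, "y", ("A", "B"), family="normal", eliminate=False)
        pred = fit.result.predict(df)
        assert np.allclose(pred, df["y"], atol=1e-10)

    def test_normal_f_matches_sums_of_squares_oracle(self, rng):
        # textbook balanced two-way ANOVA by hand-computed sums of squares
        df = balanced_two_way(rng, n_per_cell=15, effects=(1.2, -0.5, 0.3), noise=2.0)
        fit = fit_factorial(df, "y", ("A", "B"), family="normal", eliminate=False)

        grand = df["y"].mean()
        n_cell = 15
        ss_a = sum(2 * n_cell * (df[df.A == a]["y"].mean() - grand) ** 2 for a in ("a0", "a1"))
        ss_b = sum(2 * n_cell * (df[df.B == b]["y"].mean() - grand) ** 2 for b in ("b0", "b1"))
        cell_means = df.groupby(["A", "B"])["y"].mean()
        ss_cells = sum(
            n_cell * (cell_means[a, b] - grand) ** 2 for a in ("a0", "a1") for b in ("b0", "b1")
        )
        ss_ab = ss_cells - ss_a - ss_b
        sse = sum(
            ((df[(df.A == a) & (df.B == b)]["y"] - cell_means[a, b]) ** 2).sum()
            for a in ("a0", "a1")
            for b in ("b0", "b1")
        )
        mse = sse / (60 - 4)
        expected_f = {"C(A, Sum)": ss_a / mse, "C(B, Sum)": ss_b / mse,
                      "C(A, Sum):C(B, Sum)": ss_ab / mse}
        got = fit.term_tests.set_index("term")["F"]
        for term, f in expected_f.items():
            assert got[term] == pytest.approx(f, rel=1e-6)

    def test_quasi_binomial_constant_proportion(self, rng):
        # constant p: intercept ~ logit(p), factor terms eliminated
        p = 0.651
        n = rng.integers(5, 20, 160)
        k = rng.binomial(n, p)
        df = pd.DataFrame(
            {"prop": k / n, "n": n,
             "A": np.repeat(["x", "y"], 80), "B": np.tile(["u", "v"], 80)}
        )
        fit = fit_factorial(df, "prop", ("A", "B"), family="quasi_binomial", trials="n")
        assert fit.params["Intercept"] == pytest.approx(logit(0.651), abs=0.12)
        retained = fit.term_tests[fit.term_tests["retained"]]["term"]
        assert len(retained) == 0 or all("Intercept" in t for t in retained)

    def test_quasi_poisson_coefficients_equal_plain_poisson(self, rng):
        counts = rng.poisson(6.0, 80)
        df = pd.DataFrame({"y": counts, "A": np.repeat(["x", "y"], 40)})
        fit = fit_factorial(df, "y", ("A",), family="quasi_poisson", eliminate=False)
        X = sm.add_constant((df["A"] == "x").astype(float) * 2 - 1)
        plain = sm.GLM(df["y"], X, family=sm.families.Poisson()).fit()
        assert np.allclose(np.sort(np.abs(fit.params)), np.sort(np.abs(plain.params)), atol=1e-8)

    def test_dispersion_scaling_controls_type_one_error(self, rng):
        # overdispersed counts, no factor effect: the scaled test holds its
        # level while the unscaled chi-square is anticonvervative
        n_sims, n_per_group = 400, 40
        rej_scaled, rej_unscaled = 0, 0
        for _ in range(n_sims):
            mu, phi = 5.0, 2.0
            r = mu / (phi - 1.0)
            y = rng.negative_binomial(r, 1.0 / phi, size=2 * n_per_group)
            df = pd.DataFrame({"y": y, "A": np.repeat(["x", "y"], n_per_group)})
            fit = fit_factorial(df, "y", ("A",), family="quasi_poisson", eliminate=False)
            rej_scaled += fit.term_tests["p"].iloc[0] < 0.05
            unscaled = fit.result.model.fit()  # plain Poisson scale = 1
            z = unscaled.params.iloc[1] / unscaled.bse.iloc[1]
            rej_unscaled += 2 * stats.norm.sf(abs(z)) < 0.05
        assert 0.02 <= rej_scaled / n_sims <= 0.08
        assert rej_unscaled / n_sims > 0.10  # without scaling the level is inflated

    def test_empty_cell_aliasing_reported(self):
        df = balanced_two_way(effects=(1.0, 1.0, 0.0))
        df = df[~((df.A == "a1") & (df.B == "b1"))]
        with pytest.raises(ValueError, match="alias|singular"):
            fit_factorial(df, "y", ("A", "B"), family="normal", eliminate=False)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            fit_factorial(pd.DataFrame({"y": [1.0], "A": ["x"]}), "y", ("A",), family="tweedie")


class TestPosthoc:
    def _four_group_fit(self, rng, shifts=(0.0, 0.0, 0.0, 0.0), noise=1.0, n=30):
        levels = ["control", "low", "high", "both"]
        rows = []
        for lev, sh in zip(levels, shifts):
            for _ in range(n):
                rows.append({"risk": lev, "y": 10.0 + sh + rng.normal(0, noise)})
        return fit_factorial(pd.DataFrame(rows), "y", ("risk",), family="normal",
                             eliminate=False)

    def test_identical_groups_all_adjusted_p_one(self, rng):
        # the same sample replicated in every group: all contrasts exactly zero
        base = rng.normal(10.0, 1.0, 25)
        rows = [{"risk": lev, "y": y} for lev in ("control", "low", "high", "both") for y in base]
        fit = fit_factorial(pd.DataFrame(rows), "y", ("risk",), family="normal",
                            eliminate=False)
        out = posthoc_contrasts(fit, "risk", "tukey")
        assert len(out) == 6
        assert np.allclose(out["estimate"], 0.0, atol=1e-12)
        assert np.allclose(out["p_adj"], 1.0, atol=1e-9)

    def test_three_level_factor_gives_three_pairs(self, rng):
        rows = [{"g": g, "y": rng.normal()} for g in "abc" for _ in range(10)]
        fit = fit_factorial(pd.DataFrame(rows), "y", ("g",), family="normal", eliminate=False)
        assert len(posthoc_contrasts(fit, "g", "holm")) == 3

    def test_dunnett_style_control_mode(self, rng):
        fit = self._four_group_fit(rng, shifts=(0.0, 0.0, -2.0, -2.0))
        out = posthoc_contrasts(fit, "risk", "dunnett_style", control="control")
        assert len(out) == 3
        assert (out["level_1"] == "control").all()

    def test_shift_detected_with_correct_sign(self, rng):
        # known -1.2 shift of the high-risk group vs control
        fit = self._four_group_fit(rng, shifts=(0.0, 0.0, -1.2, 0.0), n=40)
        out = posthoc_contrasts(fit, "risk", "tukey")
        row = out[(out.level_1 == "control") & (out.level_2 == "high")]
        if row.empty:
            row = out[(out.level_1 == "high") & (out.level_2 == "control")]
            assert row["estimate"].iloc[0] < 0
        else:
            assert row["estimate"].iloc[0] > 0
        assert row["p_adj"].iloc[0] < 0.05

    def test_holm_adjustment_monotone(self, rng):
        fit = self._four_group_fit(rng, shifts=(0.0, 0.5, 1.0, 1.5))
        out = posthoc_contrasts(fit, "risk", "holm").sort_values("p_raw")
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()
        assert out["p_adj"].is_monotonic_increasing

    def test_absent_factor_rejected(self, rng):
        fit = self._four_group_fit(rng)
        with pytest.raises(ValueError):
            posthoc_contrasts(fit, "regime")


class TestSexRatio:
    def test_pooled_proportion_and_elimination(self, simulated_cells):
        _, eggs = simulated_cells
        fit = sex_ratio_analysis(eggs[eggs.species == "predator"])
        overall = fit.pooled[fit.pooled.level == "overall"]["pct_female"].iloc[0]
        # generator draws sex at the published per-regime female fractions
        assert overall == pytest.approx(65.1, abs=4.0)
        assert fit.family == "quasi_binomial"
        assert fit.dispersion > 0

    def test_no_sexed_eggs_rejected(self):
        eggs = pd.DataFrame({"female_id": [1], "regime": ["mild"],
                             "acclimated": [False], "sex": ["unknown"]})
        with pytest.raises(ValueError):
            sex_ratio_analysis(eggs)

    def test_boundary_all_female_flagged(self):
        eggs = pd.DataFrame(
            {"female_id": np.repeat(np.arange(10), 3), "regime": "mild",
             "acclimated": False, "sex": "female"}
        )
        with pytest.raises(ValueError, match="boundary|separation"):
            sex_ratio_analysis(eggs, factors=("regime",))
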