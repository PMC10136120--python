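import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from heatmite._reference import EGG_VOLUME_PARAMS, OVIPOSITION_PARAMS
from heatmite.rate_curves import RateCurveParams, eval_curve, fit_loglinear, fit_nls, peak_age
from heatmite.synthetic_cohort import CohortConfig, simulate_cohort

PRED_EXTREME = OVIPOSITION_PARAMS[("predator", "extreme")]
PREY_MILD = OVIPOSITION_PARAMS[("prey", "mild")]


class TestEvalCurve:
    def test_predator_extreme_peak_rate(self):
        # value at the analytic peak age -b/c, frozen from scalar evaluation
        t = 1.8765 / 0.3223
        assert eval_curve(PRED_EXTREME, t) == pytest.approx(3.7456, abs=1e-3)

    def test_constant_limit(self):
        p = RateCurveParams(a=2.5, included_terms=frozenset())
        assert eval_curve(p, 7.0) == 2.5
        assert eval_curve(p, 0.5) == 2.5

    def test_prey_mild_female_egg_volume(self):
        p = EGG_VOLUME_PARAMS[("prey", "mild", "female")]
        assert eval_curve(p, 3.5) == pytest.approx(1.168, abs=1e-3)

    def test_positive_everywhere_and_zero_at_origin(self):
        t = np.linspace(0.01, 50, 500)
        y = eval_curve(PRED_EXTREME, t)
        assert np.all(y > 0)
        assert eval_curve(PRED_EXTREME, 1e-9) < 1e-12  # b > 0 forces y -> 0

    def test_nonpositive_age_rejected_with_power_term(self):
        with pytest.raises(ValueError):
            eval_curve(PRED_EXTREME, 0.0)


class TestPeakAge:
    def test_prey_mild_closed_form(self):
        assert peak_age(PREY_MILD) == pytest.approx(2.8919 / 0.3723, abs=1e-6)
        assert peak_age(PREY_MILD) == pytest.approx(7.768, abs=1e-3)

    def test_predator_extreme_closed_form(self):
        assert peak_age(PRED_EXTREME) == pytest.approx(5.822, abs=1e-3)

    def test_monotone_curve_has_no_peak(self):
        p = RateCurveParams(a=1.0, b=2.0, c=0.1, included_terms=frozenset("bc"))
        assert peak_age(p) is None

    @pytest.mark.parametrize(
        "params",
        [
            PRED_EXTREME,
            PREY_MILD,
            EGG_VOLUME_PARAMS[("prey", "mild", "female")],
            EGG_VOLUME_PARAMS[("predator", "mild", "female")],
            RateCurveParams(a=1.0, b=1.5, c=-0.1, d=-0.02, included_terms=frozenset("bcd")),
        ],
    )
    def test_agrees_with_numeric_argmax(self, params):
        pk = peak_age(params)
        if pk is None or not (0 < pk < 50):
            return
        num = optimize.minimize_scalar(
            lambda t: -eval_curve(params, t), bounds=(1e-6, 50.0), method="bounded",
            options={"xatol": 1e-10},
        ).x
        assert pk == pytest.approx(num, abs=1e-6)


class TestFitNls:
    def _noiseless(self, params, n_rep=5):
        ages = np.tile(np.arange(3.5, 13.0, 1.0), n_rep)
        return pd.DataFrame(
            {"age": ages, "y": eval_curve(params, ages),
             "female_id": np.repeat(np.arange(n_rep), 10)}
        )

    def test_noiseless_recovery(self):
        df = self._noiseless(PRED_EXTREME)
        fit = fit_nls(df, "y", "oviposition", included_terms=("b", "c"))
        assert fit.a == pytest.approx(PRED_EXTREME.a, rel=1e-6)
        assert fit.b == pytest.approx(PRED_EXTREME.b, rel=1e-6)
        assert fit.c == pytest.approx(PRED_EXTREME.c, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.converged

    def test_single_age_unidentifiable(self):
        df = pd.DataFrame({"age": [5.0] * 20, "y": np.linspace(1, 2, 20)})
        with pytest.raises(ValueError):
            fit_nls(df, "y", "oviposition")

    def test_negative_response_rejected(self):
        df = self._noiseless(PRED_EXTREME)
        df.loc[0, "y"] = -1.0
        with pytest.raises(ValueError):
            fit_nls(df, "y", "oviposition")

    def test_r_squared_invariant_to_row_order(self, rng):
        df = self._noiseless(PREY_MILD)
        df["y"] = df["y"] + rng.normal(0, 0.3, len(df))
        fit1 = fit_nls(df, "y", "oviposition")
        fit2 = fit_nls(df.sample(frac=1.0, random_state=1), "y", "oviposition")
        assert fit1.r_squared == pytest.approx(fit2.r_squared, rel=1e-9)

    def test_recovery_from_noisy_cohort(self):
        cfg = CohortConfig(
            species="predator", acclimated=False, regime="extreme", n_females=300,
            oviposition_params=PRED_EXTREME,
            eggsize_params={
                "female": EGG_VOLUME_PARAMS[("predator", "extreme", "female")],
                "male": EGG_VOLUME_PARAMS[("predator", "extreme", "male")],
            },
            p_female=0.618,
        )
        females, _ = simulate_cohort(cfg, seed=99)
        alive = females[females["status"] == "alive"]
        fit = fit_nls(alive, "eggs", "oviposition", cluster="female_id")
        for name, truth in (("a", PRED_EXTREME.a), ("b", PRED_EXTREME.b), ("c", PRED_EXTREME.c)):
            assert abs(getattr(fit, name) - truth) < 2.5 * fit.se[name]


class TestFitLogLinear:
    def test_exact_on_noiseless_volume_model(self):
        # no +1 offset for volumes: ln y is exactly linear in the age terms
        truth = EGG_VOLUME_PARAMS[("prey", "mild", "female")]
        ages = np.tile(np.arange(3.5, 13.0, 1.0), 8)
        df = pd.DataFrame(
            {"age": ages, "vol": eval_curve(truth, ages),
             "female_id": np.repeat(np.arange(8), 10)}
        )
        fit = fit_loglinear(df, "vol", "egg_volume", included_terms=("c", "d"), eliminate=False)
        imp = fit.implied_params
        assert not fit.offset_plus_one
        assert imp.a == pytest.approx(truth.a, rel=1e-9)
        assert imp.c == pytest.approx(truth.c, rel=1e-8)
        assert imp.d == pytest.approx(truth.d, rel=1e-6)

    def test_plus_one_offset_only_for_rates(self):
        ages = np.tile(np.arange(3.5, 13.0, 1.0), 4)
        df = pd.DataFrame({"age": ages, "y": eval_curve(PREY_MILD, ages),
                           "female_id": np.repeat(np.arange(4), 10)})
        fit = fit_loglinear(df, "y", "oviposition", eliminate=False)
        assert fit.offset_plus_one

    def test_regime_effect_recovered_within_2_robust_se(self, rng):
        # ln y = b0 + b1 ln t + b2 t + regime shift + female intercept + noise
        n_per_arm, n_days = 150, 10
        shift = 0.30
        rows = []
        for arm, regime in ((0, "mild"), (1, "extreme")):
            for f in range(n_per_arm):
                u = rng.normal(0, 0.2)
                for d in range(n_days):
                    t = 3.5 + d
                    lny = 0.5 + 1.2 * np.log(t) - 0.15 * t + shift * arm + u + rng.normal(0, 0.3)
                    rows.append({"female_id": f"{regime}{f}", "age": t, "regime": regime,
                                 "y": np.exp(lny) - 1.0 + 1e-12})
        df = pd.DataFrame(rows)
        df["y"] = df["y"].clip(lower=0.0)
        fit = fit_loglinear(df, "y", "oviposition", included_terms=("b", "c"),
                            factors=("regime",), eliminate=False)
        name = [i for i in fit.params.index if "regime" in i]
        assert len(name) == 1
        # Sum coding: the retained column names one level; the extreme-vs-mild
        # difference is +/- 2x its coefficient depending on which level it is
        sign = 1.0 if "extreme" in name[0] else -1.0
        est = sign * 2.0 * fit.params[name[0]]
        se = 2.0 * fit.bse[name[0]]
        assert abs(est - shift) < 2 * se

    def test_null_factor_eliminated(self, rng):
        ages = np.tile(np.arange(3.5, 13.0, 1.0), 60)
        df = pd.DataFrame(
            {"age": ages, "female_id": np.repeat(np.arange(60), 10),
             "regime": np.repeat(["mild", "extreme"] * 30, 10)}
        )
        df["y"] = eval_curve(PREY_MILD, df["age"].to_numpy()) * rng.lognormal(0, 0.2, len(df))
        fit = fit_loglinear(df, "y", "oviposition", included_terms=("b", "c"),
                            factors=("regime",))
        dropped = [t for t, _, _ in fit.elimination_trace]
        assert any("regime" in t for t in dropped)

    def test_all_zero_response_degenerate(self):
        df = pd.DataFrame({"age": [3.5, 4.5, 5.5, 6.5], "y": 0.0, "female_id": [0, 0, 1, 1]})
        with pytest.raises(ValueError):
            fit_loglinear(df, "y", "oviposition")
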