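"""Cox fits, the sequential adjustment ladder, restricted cubic splines,
and survival curves."""

import numpy as np
import pandas as pd
import pytest

from phenoaccel.analysis.splines import default_knots, rcs_basis, spline_hazard_curve
from phenoaccel.analysis.survival import (
    adjusted_survival_curves,
    cox_fit,
    km_curves,
    sequential_cox,
)


class TestCoxFit:
    def test_three_observation_closed_form(self):
        # risk sets give dlogPL/dbeta = 0 at exp(beta) = 1/sqrt(2)
        model = cox_fit([1.0, 2.0, 3.0], [1, 1, 1], np.array([[1.0], [0.0], [1.0]]), ["x"])
        assert model.coefficients[0] == pytest.approx(-0.5 * np.log(2), abs=1e-6)
        assert model.hazard_ratios[0] == pytest.approx(2 ** -0.5, abs=1e-6)

    def test_constant_covariate_reports_unit_hazard_ratio(self):
        model = cox_fit([1.0, 2, 3, 4], [1, 0, 1, 1], np.ones((4, 1)), ["c"])
        assert model.hazard_ratios[0] == 1.0
        assert model.concordance == 0.5

    def test_duplicating_rows_leaves_coefficient_unchanged(self):
        # exact partial-likelihood invariance holds under Breslow ties
        # (the duplicated likelihood is the square of the original); Efron
        # downweights the ties duplication creates, so the packaged fit is
        # only nearly invariant
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(5)
        n = 80
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0, n) * np.exp(-0.5 * x)
        e = np.ones(n, dtype=int)
        m1 = cox_fit(t, e, x[:, None], ["x"])

        def breslow(times, events, xs):
            def neg_logpl(beta):
                ll = 0.0
                for i in np.nonzero(events)[0]:
                    at_risk = times >= times[i]
                    ll += xs[i] * beta - np.log(np.exp(xs[at_risk] * beta).sum())
                return -ll
            return minimize_scalar(neg_logpl, bounds=(-5, 5), method="bounded",
                                   options={"xatol": 1e-10}).x

        assert breslow(np.r_[t, t], np.r_[e, e], np.r_[x, x]) == pytest.approx(
            breslow(t, e, x), abs=1e-6
        )
        m2 = cox_fit(np.r_[t, t], np.r_[e, e], np.r_[x, x][:, None], ["x"])
        assert m2.coefficients[0] == pytest.approx(m1.coefficients[0], abs=0.05)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit([1.0, 2.0], [0, 0], np.array([[1.0], [0.0]]), ["x"])

    def test_true_risk_score_beats_random_score_in_concordance(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, 500)
            t = r.exponential(1.0, 500) * np.exp(-0.8 * x)
            e = (r.random(500) < 0.7).astype(int)
            good = cox_fit(t, e, x[:, None], ["x"])
            noise = cox_fit(t, e, r.normal(0, 1, 500)[:, None], ["noise"])
            assert good.concordance > noise.concordance


class TestSequentialCox:
    @staticmethod
    def _toy_cohort(n=20_000, seed=0):
        rng = np.random.default_rng(seed)
        focal = rng.integers(0, 2, n).astype(float)
        indep = rng.integers(0, 2, n).astype(float)  # independent of all
        t = rng.exponential(30.0, n) * np.exp(-np.log(2) * focal)
        discharge = rng.exponential(12.0, n)
        died = t < discharge
        return pd.DataFrame({
            "time_days": np.where(died, t, discharge),
            "died_in_hospital": died.astype(int),
            "focal": focal,
            "indep": indep,
        })

    def test_empty_adjusters_equals_univariable_fit(self):
        df = self._toy_cohort(n=2000, seed=1)
        ladder = sequential_cox(df, "focal", [])
        assert len(ladder.rows) == 1
        uni = cox_fit(df["time_days"], df["died_in_hospital"],
                      df[["focal"]].to_numpy(), ["focal"])
        assert ladder.rows[0].focal_hr == pytest.approx(uni.hazard_ratios[0])
        assert ladder.final_model.names == ["focal"]

    def test_independent_adjuster_barely_moves_focal_hazard_ratio(self):
        df = self._toy_cohort(n=20_000, seed=2)
        ladder = sequential_cox(df, "focal", ["indep"])
        assert abs(ladder.rows[1].focal_hr - ladder.rows[0].focal_hr) < 0.02

    def test_ladder_shape_and_order(self):
        df = self._toy_cohort(n=3000, seed=3)
        df["extra"] = np.random.default_rng(0).integers(0, 2, len(df))
        ladder = sequential_cox(df, "focal", ["indep", "extra"])
        assert len(ladder.rows) == 3
        assert ladder.rows[2].model_terms == ["focal", "indep", "extra"]

    def test_missing_values_handled_complete_case(self):
        df = self._toy_cohort(n=1000, seed=4)
        df.loc[:49, "indep"] = np.nan
        ladder = sequential_cox(df, "focal", ["indep"])
        assert ladder.rows[0].n_excluded_missing == 0
        assert ladder.rows[1].n_excluded_missing == 50
        assert ladder.rows[1].n_used == 950

    def test_unknown_covariate_rejected(self):
        df = self._toy_cohort(n=200, seed=5)
        with pytest.raises(ValueError):
            sequential_cox(df, "nope", [])


class TestRcsBasis:
    KNOTS = np.array([-10.0, 0.0, 10.0, 30.0])

    def test_below_first_knot_nonlinear_terms_vanish(self):
        b = rcs_basis(np.array([-25.0, -11.0]), self.KNOTS)
        assert np.allclose(b[:, 1:], 0.0)

    def test_linear_beyond_last_knot(self):
        x0 = self.KNOTS[-1] + 10.0
        h = 0.5
        b = rcs_basis(np.array([x0 - h, x0, x0 + h]), self.KNOTS)
        second_diff = b[0] - 2 * b[1] + b[2]
        assert np.max(np.abs(second_diff)) < 1e-6

    def test_hand_evaluated_truncated_power_formula_between_knots(self):
        # x = 5 lies between knots 2 and 3; only the (x - t1)+ cube is live
        t = self.KNOTS
        x = 5.0
        expected = (x - t[0]) ** 3 / (t[-1] - t[0]) ** 2
        b = rcs_basis(np.array([x]), t)
        assert b[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_unsorted_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.array([1.0]), [0.0, 5.0, 3.0, 8.0])

    def test_continuity_at_knots(self):
        for k in self.KNOTS:
            b = rcs_basis(np.array([k - 1e-9, k + 1e-9]), self.KNOTS)
            assert np.allclose(b[0], b[1], atol=1e-6)

    def test_linear_function_reproduced_exactly(self):
        # regressing a linear target on the basis puts nothing on the
        # nonlinear columns
        rng = np.random.default_rng(8)
        x = rng.uniform(-20, 50, 400)
        y = 3.0 + 0.25 * x
        basis = rcs_basis(x, self.KNOTS)
        X = np.column_stack([np.ones_like(x), basis])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(beta[2:], 0.0, atol=1e-8)
        assert beta[1] == pytest.approx(0.25, abs=1e-10)


def _spline_cohort(rng, n, slope=0.06, plateau_at=None):
    """Survival data whose log hazard is (piecewise) linear in a residual."""
    resid = rng.normal(0, 12, n)
    eff = np.where(resid > plateau_at, plateau_at, resid) if plateau_at is not None else resid
    t = rng.exponential(30.0, n) * np.exp(-slope * eff)
    discharge = rng.exponential(10.0, n)
    died = t < discharge
    return np.where(died, t, discharge), died.astype(int), resid


class TestSplineHazardCurve:
    def test_curve_is_zero_at_reference(self):
        rng = np.random.default_rng(9)
        t, e, resid = _spline_cohort(rng, 1500)
        curve = spline_hazard_curve(t, e, resid, grid=np.array([0.0, 5.0]))
        assert curve.log_hr[0] == pytest.approx(0.0, abs=1e-12)

    def test_linear_truth_rarely_flags_nonlinearity(self):
        # type-I error of the joint nonlinearity test at alpha = 0.05
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            t, e, resid = _spline_cohort(rng, 1200)
            curve = spline_hazard_curve(t, e, resid, grid=np.array([0.0]))
            if curve.nonlinearity_p < 0.05:
                rejections += 1
        assert rejections <= 10

    def test_plateau_truth_recovers_flattening_beyond_cutoff(self):
        # slope of the fitted curve beyond +20 y smaller than below, most seeds
        flatter = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(2000 + seed)
            t, e, resid = _spline_cohort(rng, 4000, slope=0.08, plateau_at=12.0)
            grid = np.array([-10.0, 10.0, 20.0, 35.0])
            curve = spline_hazard_curve(t, e, resid, grid=grid)
            slope_below = (curve.log_hr[1] - curve.log_hr[0]) / 20.0
            slope_above = (curve.log_hr[3] - curve.log_hr[2]) / 15.0
            if slope_above < slope_below:
                flatter += 1
        assert flatter >= 24  # sign test: one-sided binomial p < 1e-3 under 50/50


class TestSurvivalCurves:
    @staticmethod
    def _cohort(n=800, seed=12):
        rng = np.random.default_rng(seed)
        accel = rng.integers(0, 2, n).astype(float)
        age = rng.uniform(30, 90, n)
        t = rng.exponential(40.0, n) * np.exp(-0.8 * accel)
        discharge = rng.exponential(10.0, n)
        died = t < discharge
        return pd.DataFrame({
            "time_days": np.where(died, t, discharge),
            "died_in_hospital": died.astype(int),
            "phenoage_accel": accel,
            "age_years": age,
        })

    def test_km_curves_monotone_and_logrank_detects_gap(self):
        df = self._cohort()
        out = km_curves(df["time_days"], df["died_in_hospital"], df["phenoage_accel"])
        assert out["logrank_p"] < 0.01
        for curve in out["curves"].values():
            s = curve["survival"].to_numpy()
            assert np.all(np.diff(s) <= 1e-12)

    def test_adjusted_curves_order_groups_correctly(self):
        df = self._cohort()
        out = adjusted_survival_curves(df, "phenoage_accel", ["age_years"])
        s0 = out["0"]["survival"].to_numpy()
        s1 = out["1"]["survival"].to_numpy()
        assert s1[-1] < s0[-1]  # accelerated group survives less
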