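"""Standard curves, initial rates, MM/Hill fitting and fold spreads."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from eraptype.kinetics import (
    ActivityProfile,
    efficiency_from_linear_regime,
    fit_hill,
    fit_mm,
    fit_standard_curve,
    fold_ratios,
    initial_rate,
    model_select,
    specific_activity,
)
from eraptype.synthdata import HillTruth, MMTruth, gen_rate_dataset


class TestStandardCurve:
    def test_two_point_line(self):
        curve = fit_standard_curve([0.0, 1.0], [0.0, 10.0])
        assert curve.slope == pytest.approx(10.0)
        assert curve.intercept == pytest.approx(0.0)

    def test_noiseless_slope_recovered_exactly(self):
        conc = np.linspace(0, 5e-6, 6)
        curve = fit_standard_curve(conc, 3.7e6 * conc + 12.0)
        assert curve.slope == pytest.approx(3.7e6)
        assert curve.intercept == pytest.approx(12.0)

    def test_noisy_fit_matches_normal_equations(self, rng):
        conc = np.linspace(0, 1e-5, 8)
        signal = 2.0e6 * conc + 5.0 + rng.normal(0, 0.5, 8)
        curve = fit_standard_curve(conc, signal)
        # closed-form least squares oracle
        x = np.column_stack([conc, np.ones_like(conc)])
        beta = np.linalg.solve(x.T @ x, x.T @ signal)
        assert curve.slope == pytest.approx(beta[0], rel=1e-9)
        assert curve.intercept == pytest.approx(beta[1], rel=1e-9)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_standard_curve([1.0, 1.0], [2.0, 2.1])

    @given(st.floats(min_value=1e-9, max_value=1e-3))
    def test_apply_invert_round_trip(self, conc):
        curve = fit_standard_curve([0.0, 1e-3], [3.0, 2003.0])
        assert curve.invert(curve.apply(conc)) == pytest.approx(conc, rel=1e-9)


class TestInitialRate:
    def test_exact_linear_course_returns_slope(self):
        t = np.arange(10.0)
        est = initial_rate(t, 2e-9 * t, s0=1e-6)
        assert est.rate == pytest.approx(2e-9, rel=1e-12)

    def test_constant_course_gives_zero(self):
        est = initial_rate(np.arange(6.0), np.zeros(6))
        assert est.rate == 0.0

    def test_mm_progress_curve_matches_closed_form_rate(self):
        # independently integrated progress curve
        kcat, km, e, s0 = 10.0, 50e-6, 25e-9, 25e-6
        sol = solve_ivp(
            lambda _t, p: [kcat * e * (s0 - p[0]) / (km + (s0 - p[0]))],
            (0, 40), [0.0], t_eval=np.linspace(0, 40, 41), rtol=1e-10,
        )
        # a 5% depletion window keeps the secant slope within 3% of the
        # instantaneous initial rate at this S ~ KM/2 design
        est = initial_rate(sol.t, sol.y[0], s0=s0, max_fraction=0.05)
        v0 = kcat * e * s0 / (km + s0)
        assert est.rate == pytest.approx(v0, rel=0.03)

    def test_window_excludes_depleted_points(self):
        t = np.linspace(0, 200, 101)
        p = 1e-6 * (1 - np.exp(-0.005 * t))  # saturating course
        est = initial_rate(t, p, s0=1e-6, max_fraction=0.10)
        assert p[np.searchsorted(t, est.t_max)] <= 0.10 * 1e-6 + 1e-18
        assert est.n_points < len(t)

    def test_too_few_eligible_points_rejected(self):
        with pytest.raises(ValueError, match="turnover window"):
            initial_rate([0.0, 1, 2, 3], [0.0, 0.5, 0.9, 1.0], s0=1.0)


class TestSpecificActivity:
    def test_arithmetic(self):
        assert specific_activity(2.5e-9, 25e-9) == pytest.approx(0.1)

    def test_zero_rate(self):
        assert specific_activity(0.0, 1e-9) == 0.0

    def test_nonpositive_enzyme_rejected(self):
        with pytest.raises(ValueError):
            specific_activity(1e-9, 0.0)

    def test_replicate_batch_matches_hand_computation(self):
        rates = np.array([2.0e-9, 2.2e-9, 1.8e-9])
        acts = [specific_activity(r, 20e-9) for r in rates]
        assert np.mean(acts) == pytest.approx(0.1)
        assert np.std(acts, ddof=1) == pytest.approx(np.std(rates / 20e-9, ddof=1))


class TestLinearRegime:
    def test_exactly_proportional_data_recovers_constant(self):
        s = np.linspace(1e-6, 20e-6, 6)
        res = efficiency_from_linear_regime(s, 5e4 * s)
        assert res.efficiency == pytest.approx(5e4)
        assert not res.nonlinear

    def test_low_substrate_mm_data_within_5_percent(self):
        truth = MMTruth(kcat=5.0, km=100e-6)
        s = np.linspace(1e-6, truth.km / 20, 8)
        v_over_e = truth.rate(1.0, s)  # E=1 -> v/E
        res = efficiency_from_linear_regime(s, v_over_e)
        assert res.efficiency == pytest.approx(truth.efficiency, rel=0.05)

    def test_saturating_data_flagged_nonlinear(self):
        truth = MMTruth(kcat=5.0, km=100e-6)
        s = np.linspace(20e-6, 2 * truth.km, 8)
        res = efficiency_from_linear_regime(s, truth.rate(1.0, s))
        assert res.nonlinear
        with pytest.raises(ValueError, match="nonlinear"):
            efficiency_from_linear_regime(s, truth.rate(1.0, s), strict=True)


class TestMMFit:
    S12 = np.geomspace(5e-6, 500e-6, 12)

    def test_noiseless_grid_recovered_exactly(self):
        truth = MMTruth(10.0, 50e-6)
        fit = fit_mm(self.S12, truth.rate(25e-9, self.S12), 25e-9)
        assert fit.kcat == pytest.approx(10.0, rel=1e-6)
        assert fit.km == pytest.approx(50e-6, rel=1e-6)
        assert fit.converged

    def test_noisy_fit_within_15_percent(self):
        truth = MMTruth(10.0, 50e-6)
        data = gen_rate_dataset(truth, self.S12, 25e-9, 0.05, seed=11)
        fit = fit_mm(data["s"], data["rate"], 25e-9)
        assert fit.kcat == pytest.approx(truth.kcat, rel=0.15)
        assert fit.km == pytest.approx(truth.km, rel=0.15)

    def test_cooperative_data_prefers_hill_by_aic(self):
        truth = HillTruth(2.5e-7, 50e-6, 2.0)
        v = truth.rate(self.S12)
        choice = model_select(fit_mm(self.S12, v, 1e-9), fit_hill(self.S12, v, 1e-9))
        assert choice.chosen == "hill"

    def test_parameter_recovery_median_bias_below_5_percent(self):
        truth = MMTruth(6.0, 30e-6)
        s = np.geomspace(5e-6, 500e-6, 16)
        kcat_bias, km_bias = [], []
        for seed in range(100):
            data = gen_rate_dataset(truth, s, 1e-9, 0.05, seed=seed)
            fit = fit_mm(data["s"], data["rate"], 1e-9)
            kcat_bias.append(abs(fit.kcat / truth.kcat - 1))
            km_bias.append(abs(fit.km / truth.km - 1))
        assert np.median(kcat_bias) < 0.05
        assert np.median(km_bias) < 0.05


class TestHillFit:
    S = np.geomspace(10e-6, 1e-3, 10)

    def test_fixed_h1_reduces_to_mm(self):
        truth = MMTruth(4.0, 80e-6)
        data = gen_rate_dataset(truth, self.S, 1e-9, 0.05, seed=5)
        mm = fit_mm(data["s"], data["rate"], 1e-9)
        hill = fit_hill(data["s"], data["rate"], 1e-9, fix_h=1.0)
        assert hill.kcat == pytest.approx(mm.kcat, rel=1e-4)
        assert hill.k_half == pytest.approx(mm.km, rel=1e-4)

    def test_noiseless_recovery(self):
        truth = HillTruth(3.0e-7, 250e-6, 1.5)
        fit = fit_hill(self.S, truth.rate(self.S))
        assert fit.vmax == pytest.approx(truth.vmax, rel=1e-6)
        assert fit.k_half == pytest.approx(truth.k_half, rel=1e-6)
        assert fit.h == pytest.approx(1.5, rel=1e-6)

    def test_noisy_cooperative_h_in_band(self):
        truth = HillTruth(3.0e-7, 100e-6, 2.0)
        rng = np.random.default_rng(17)
        v = truth.rate(self.S)
        sigma = np.sqrt(np.log1p(0.05**2))
        v = v * rng.lognormal(-0.5 * sigma**2, sigma, v.shape)
        fit = fit_hill(self.S, v)
        assert 1.6 <= fit.h <= 2.4


class TestModelSelect:
    S = np.geomspace(5e-6, 500e-6, 12)

    def test_mm_data_selects_mm_by_parsimony(self):
        truth = MMTruth(5.0, 60e-6)
        v = truth.rate(1e-9, self.S)
        choice = model_select(fit_mm(self.S, v, 1e-9), fit_hill(self.S, v, 1e-9))
        assert choice.chosen == "mm"
        assert abs(choice.delta_aic) <= 2.0 or choice.delta_aic < 0


class TestFoldRatios:
    def _profile(self, values):
        return ActivityProfile(
            pd.DataFrame(
                {
                    "allotype": list(values),
                    "substrate": "YTAFTIPSI",
                    "value": list(values.values()),
                }
            )
        )

    def test_sixty_fold_pair(self):
        prof = self._profile({"2": 60.0, "10": 1.0})
        ratios = fold_ratios(prof, "YTAFTIPSI")
        assert ratios.matrix.loc["2", "10"] == pytest.approx(60.0)
        assert ratios.spread == pytest.approx(60.0)

    def test_identical_values_all_ratios_one(self):
        prof = self._profile({"1": 3.0, "2": 3.0, "3": 3.0})
        ratios = fold_ratios(prof, "YTAFTIPSI")
        assert np.allclose(ratios.matrix.to_numpy(), 1.0)
        assert ratios.spread == 1.0

    def test_three_allotype_hand_computation(self):
        prof = self._profile({"1": 6.0, "2": 3.0, "3": 2.0})
        ratios = fold_ratios(prof, "YTAFTIPSI")
        assert ratios.matrix.loc["1", "3"] == pytest.approx(3.0)
        assert ratios.matrix.loc["2", "3"] == pytest.approx(1.5)
        assert ratios.matrix.loc["3", "1"] == pytest.approx(1 / 3)

    def test_missing_value_excluded_not_fabricated(self):
        prof = ActivityProfile(
            pd.DataFrame(
                {
                    "allotype": ["2", "3", "10"],
                    "substrate": "Leu-pNA",
                    "value": [3.0, 2.0, np.nan],
                }
            )
        )
        ratios = fold_ratios(prof, "Leu-pNA")
        assert ratios.excluded == ("10",)
        assert "10" not in ratios.matrix.index
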