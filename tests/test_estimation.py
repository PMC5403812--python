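"""Fitting layer: orthogonal residuals, turnover and exposure estimation."""

import numpy as np
import pytest

from glucotrace.estimation import (OrthoResidualConfig, fit_kh, fit_meal_cho,
                                   fit_required_auc, lifespan,
                                   orthogonal_residuals)
from glucotrace.kh_turnover import KhParams, LabelCurve, simulate_kh
from glucotrace.square_pulse import EnrichmentSamples, build_square_pulse
from glucotrace.tracer_simulator import (InfusionSegment, MealEvent, Protocol,
                                         Subject, build_params, simulate)

OBS_DAYS = np.array([1.0, 3.0, 5.0, 7.0, 10.0, 14.0, 17.0, 21.0])


def _unit_pulse_profile(auc=25.0, end_h=24.0, horizon_h=600.0):
    return build_square_pulse(auc, 0.0, end_h).render(
        np.linspace(0.0, horizon_h, 5))


class TestOrthogonalResiduals:
    def test_point_on_curve_has_zero_residual(self):
        t = np.linspace(0, 10, 1001)
        y = np.sin(t)
        cfg = OrthoResidualConfig(5.0, 3.0, 0.0, 0.5)
        r = orthogonal_residuals(t, y, np.array([t[300]]),
                                 np.array([y[300]]), cfg)
        assert r[0] == 0.0

    def test_vertical_offset_from_horizontal_line(self):
        t = np.linspace(0, 10, 2001)
        y = np.full_like(t, 0.3)
        cfg = OrthoResidualConfig(5.0, 2.0, 0.3, 0.05)
        delta = 0.01
        r = orthogonal_residuals(t, y, np.array([4.0]),
                                 np.array([0.3 + delta]), cfg)
        assert r[0] == pytest.approx(delta / 0.05, rel=1e-6)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            OrthoResidualConfig(0.0, 1.0, 0.0, 0.0)

    def test_empty_data_rejected(self):
        cfg = OrthoResidualConfig(0.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            orthogonal_residuals(np.arange(3.0), np.arange(3.0),
                                 np.array([]), np.array([]), cfg)


class TestFitKh:
    def test_noise_free_recovery(self):
        u = _unit_pulse_profile()
        truth = KhParams(p=0.01, d_star=0.05)
        data = LabelCurve(t=OBS_DAYS,
                          l_star=simulate_kh(u, truth, OBS_DAYS).l_star)
        fit = fit_kh(data, u, seed=1, n_starts=100)
        assert fit.estimates["p"] == pytest.approx(0.01, rel=1e-4)
        assert fit.estimates["d_star"] == pytest.approx(0.05, rel=1e-4)

    def test_all_zero_data_pins_p_at_zero(self):
        u = _unit_pulse_profile()
        data = LabelCurve(t=OBS_DAYS, l_star=np.zeros_like(OBS_DAYS))
        fit = fit_kh(data, u, seed=1, n_starts=50)
        assert fit.estimates["p"] < 1e-8
        assert fit.at_bound["p"]

    def test_deterministic_given_seed(self):
        u = _unit_pulse_profile()
        truth = KhParams(p=0.02, d_star=0.1)
        noisy = simulate_kh(u, truth, OBS_DAYS).l_star * 1.05
        data = LabelCurve(t=OBS_DAYS, l_star=noisy)
        f1 = fit_kh(data, u, seed=11, n_starts=60)
        f2 = fit_kh(data, u, seed=11, n_starts=60)
        assert f1.estimates == f2.estimates

    def test_too_few_points_rejected(self):
        u = _unit_pulse_profile()
        data = LabelCurve(t=OBS_DAYS[:2], l_star=np.zeros(2))
        with pytest.raises(ValueError):
            fit_kh(data, u, seed=1)

    def test_inflated_exposure_deflates_p_proportionally(self):
        """Scaling the assumed U by k scales the fitted p by ~1/k."""
        u = _unit_pulse_profile(auc=25.0)
        truth = KhParams(p=0.01, d_star=0.05)
        data = LabelCurve(t=OBS_DAYS,
                          l_star=simulate_kh(u, truth, OBS_DAYS).l_star)
        for k in (0.5, 2.0):
            u_k = _unit_pulse_profile(auc=25.0 * k)
            fit = fit_kh(data, u_k, seed=5, n_starts=100)
            assert fit.estimates["p"] == pytest.approx(0.01 / k, rel=1e-3)

    def test_recovery_under_multiplicative_noise(self):
        """50 synthetic subjects, 10% CV noise: median |rel err| < 10%,
        and no systematic sign bias in the p errors."""
        from scipy.stats import binomtest
        u = _unit_pulse_profile()
        rng = np.random.default_rng(123)
        sigma = np.sqrt(np.log1p(0.10 ** 2))
        errors = []
        for i in range(50):
            truth = KhParams(p=rng.uniform(0.003, 0.03),
                             d_star=rng.uniform(0.01, 0.2))
            clean = simulate_kh(u, truth, OBS_DAYS).l_star
            obs = clean * np.exp(rng.normal(-sigma ** 2 / 2, sigma,
                                            len(OBS_DAYS)))
            fit = fit_kh(LabelCurve(t=OBS_DAYS, l_star=obs), u,
                         seed=i, n_starts=100)
            errors.append((fit.estimates["p"] - truth.p) / truth.p)
        errors = np.array(errors)
        assert np.median(np.abs(errors)) < 0.10
        n_pos = int((errors > 0).sum())
        assert binomtest(n_pos, len(errors)).pvalue > 0.05


class TestFitRequiredAuc:
    P_FIXED = {"cd4": 1.0 / 210.0, "cd8": 1.0 / 341.0}

    def _data(self, auc, p_scale=1.0, d4=0.08, d8=0.04):
        u = _unit_pulse_profile(auc=auc)
        cd4 = simulate_kh(u, KhParams(self.P_FIXED["cd4"] * p_scale, d4),
                          OBS_DAYS)
        cd8 = simulate_kh(u, KhParams(self.P_FIXED["cd8"] * p_scale, d8),
                          OBS_DAYS)
        return (LabelCurve(t=OBS_DAYS, l_star=cd4.l_star),
                LabelCurve(t=OBS_DAYS, l_star=cd8.l_star))

    def test_noise_free_joint_recovery(self):
        cd4, cd8 = self._data(auc=75.0)
        fit = fit_required_auc(cd4, cd8, self.P_FIXED, window=(0.0, 24.0),
                               seed=3, n_starts=100)
        assert fit.estimates["auc"] == pytest.approx(75.0, rel=0.01)
        assert not fit.at_bound["auc"]

    def test_unreconcilable_data_pins_auc_at_bound(self):
        # data generated with 6x the fixed proliferation rates would need
        # ~6x the exposure: the estimate must pin at the upper bound
        cd4, cd8 = self._data(auc=75.0, p_scale=6.0)
        fit = fit_required_auc(cd4, cd8, self.P_FIXED, window=(0.0, 24.0),
                               seed=3, n_starts=60)
        assert fit.estimates["auc"] == pytest.approx(100.0, rel=1e-6)
        assert fit.at_bound["auc"]

    def test_deterministic_given_seed(self):
        cd4, cd8 = self._data(auc=60.0)
        f1 = fit_required_auc(cd4, cd8, self.P_FIXED, window=(0.0, 24.0),
                              seed=9, n_starts=60)
        f2 = fit_required_auc(cd4, cd8, self.P_FIXED, window=(0.0, 24.0),
                              seed=9, n_starts=60)
        assert f1.estimates == f2.estimates

    def test_invalid_fixed_rates_rejected(self):
        cd4, cd8 = self._data(auc=60.0)
        with pytest.raises(ValueError):
            fit_required_auc(cd4, cd8, {"cd4": 0.0, "cd8": 0.01},
                             window=(0.0, 24.0))


class TestFitMealCho:
    def test_recovers_true_meal_size_from_clean_samples(self):
        subject = Subject(weight=70.0)
        params = build_params(subject)
        true_proto = Protocol(
            subject=subject,
            infusions=(InfusionSegment(0.0, 24.0, 2.7, prime=4.6),),
            meals=(MealEvent(time=8.0, cho=80.0),
                   MealEvent(time=14.0, cho=50.0)),
            horizon=28.0)
        grid = np.arange(0.0, 28.01, 0.1)
        traj = simulate(true_proto, params, grid)
        t_obs = np.array([2.0, 6.0, 8.5, 9.5, 11.0, 13.0, 15.0, 18.0,
                          22.0, 26.0])
        samples = EnrichmentSamples(t=t_obs, e=traj.enrichment(t_obs),
                                    label_start=0.0, label_end=24.0)
        start_proto = Protocol(
            subject=subject, infusions=true_proto.infusions,
            meals=(MealEvent(time=8.0, cho=40.0),
                   MealEvent(time=14.0, cho=50.0)),
            horizon=28.0)
        fit = fit_meal_cho(start_proto, samples, [0], bounds=(0.0, 200.0),
                           seed=1, params=params, grid_step=0.1,
                           n_restarts=1)
        assert fit.estimates["meal_0_cho"] == pytest.approx(80.0, abs=2.0)

    def test_no_free_meals_returns_fixed_objective(self):
        subject = Subject(weight=70.0)
        params = build_params(subject)
        proto = Protocol(subject=subject,
                         infusions=(InfusionSegment(0.0, 12.0, 2.0),),
                         horizon=14.0)
        samples = EnrichmentSamples(t=np.array([2.0, 6.0, 10.0]),
                                    e=np.array([0.1, 0.15, 0.18]),
                                    label_start=0.0, label_end=12.0)
        fit = fit_meal_cho(proto, samples, [], bounds=(0.0, 200.0),
                           seed=1, params=params, grid_step=0.2)
        assert fit.estimates == {}
        assert fit.objective >= 0

    def test_unconstrained_meal_warns(self):
        subject = Subject(weight=70.0)
        params = build_params(subject)
        proto = Protocol(subject=subject,
                         infusions=(InfusionSegment(0.0, 12.0, 2.0),),
                         meals=(MealEvent(time=10.0, cho=50.0),),
                         horizon=14.0)
        samples = EnrichmentSamples(t=np.array([2.0, 4.0, 6.0]),
                                    e=np.array([0.1, 0.15, 0.18]),
                                    label_start=0.0, label_end=12.0)
        with pytest.warns(UserWarning, match="unconstrained"):
            fit_meal_cho(proto, samples, [0], bounds=(0.0, 100.0),
                         seed=1, params=params, grid_step=0.2, n_restarts=0)


class TestLifespan:
    @pytest.mark.parametrize("p,days", [(0.01, 100.0), (1 / 210, 210.0)])
    def test_reciprocal(self, p, days):
        assert lifespan(p) == pytest.approx(days)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            lifespan(0.0)
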