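"""Exponential-rate regression and CTMI thermal-response fitting."""

import numpy as np
import pytest

from synrecruit.errors import (
    InsufficientDataError,
    UnfittableError,
    ValidationError,
)
from synrecruit.growth import (
    CardinalParams,
    GrowthCurve,
    RateMeasurement,
    ctmi_confidence_intervals,
    ctmi_mu,
    ctmi_phi,
    fit_ctmi,
    fit_exponential_rate,
)


def curve(times, densities, strain="s", temp=20.0, rep=1):
    return GrowthCurve(strain, temp, rep, np.asarray(times), np.asarray(densities))


def make_rates(temps, mus, strain="s"):
    return [
        RateMeasurement(strain, float(t), float(m), 0.01, 8, (0.0, 7.0))
        for t, m in zip(temps, mus)
    ]


class TestExponentialRate:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(0.0, 5.0)
        c = curve(t, 1e4 * np.exp(0.5 * t))
        r = fit_exponential_rate(c)
        assert r.mu == pytest.approx(0.5, abs=1e-12)
        assert not r.clamped

    def test_constant_density_gives_zero_rate(self):
        r = fit_exponential_rate(curve(np.arange(5.0), np.full(5, 1e6)))
        assert r.mu == 0.0 and r.clamped

    def test_declining_culture_clamped_to_zero(self):
        t = np.arange(6.0)
        r = fit_exponential_rate(curve(t, 1e6 * np.exp(-0.3 * t)))
        assert r.mu == 0.0 and r.clamped

    def test_window_restricts_the_regression(self):
        # exponential for 5 days then plateau; the auto window must avoid
        # diluting the slope with stationary-phase points
        t = np.arange(0.0, 10.0)
        n = np.minimum(1e4 * np.exp(0.8 * t), 1e4 * np.exp(0.8 * 5))
        r = fit_exponential_rate(curve(t, n))
        assert r.mu == pytest.approx(0.8, rel=1e-6)
        explicit = fit_exponential_rate(curve(t, n), window=(0.0, 4.0))
        assert explicit.mu == pytest.approx(0.8, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_exponential_rate(curve([0.0, 1.0], [1e4, 2e4]))
        with pytest.raises(InsufficientDataError):
            fit_exponential_rate(curve(np.arange(5.0), 1e4 * np.exp(np.arange(5.0))),
                                 window=(0.0, 1.0))

    def test_non_positive_density_rejected(self):
        with pytest.raises(ValidationError):
            curve([0.0, 1.0, 2.0], [1e4, 0.0, 1e4])

    def test_unbiased_under_lognormal_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(8.0)
        sigma = np.sqrt(np.log1p(0.05**2))
        estimates = [
            fit_exponential_rate(
                curve(t, 1e4 * np.exp(0.8 * t) * rng.lognormal(0, sigma, t.size))
            ).mu
            for _ in range(500)
        ]
        assert abs(np.mean(estimates) - 0.8) < 0.02


class TestCTMICurve:
    def test_value_at_optimum_is_mu_opt(self):
        p = CardinalParams(0.0, 24.0, 28.0, 0.9)
        assert ctmi_mu(24.0, p) == pytest.approx(0.9)

    def test_zero_outside_cardinal_range(self):
        p = CardinalParams(5.0, 24.0, 28.0, 0.9)
        assert ctmi_mu(29.0, p) == 0.0
        assert ctmi_mu(28.0, p) == 0.0
        assert ctmi_mu(4.0, p) == 0.0

    def test_hand_evaluated_point(self):
        # phi(20) = (-8 * 400) / (24 * (-96 - 64)) = 5/6
        p = CardinalParams(0.0, 24.0, 28.0, 1.0)
        assert ctmi_mu(20.0, p) == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_phi_is_one_at_topt_for_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            t_min = rng.uniform(-20, 15)
            t_opt = t_min + rng.uniform(1, 25)
            t_max = t_opt + rng.uniform(1, 10)
            assert ctmi_phi(t_opt, t_min, t_opt, t_max) == pytest.approx(1.0)

    def test_continuity_near_boundaries(self):
        p = CardinalParams(2.0, 24.0, 28.0, 0.9)
        grid = np.linspace(2.0 + 1e-9, 28.0 - 1e-9, 5001)
        mu = ctmi_mu(grid, p)
        assert mu[0] < 1e-6 and mu[-1] < 1e-6
        assert np.all(mu >= 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            ctmi_mu(20.0, CardinalParams(24.0, 24.0, 28.0, 0.9))
        with pytest.raises(ValidationError):
            ctmi_mu(20.0, CardinalParams(0.0, 24.0, 28.0, -0.1))


class TestFitCTMI:
    TRUTH = CardinalParams(2.0, 24.0, 28.0, 0.9)

    def noiseless_rates(self, temps=None):
        temps = np.arange(10.0, 34.0) if temps is None else temps
        return make_rates(temps, [ctmi_mu(t, self.TRUTH) for t in temps])

    def test_noiseless_recovery(self):
        fit = fit_ctmi(self.noiseless_rates(), seed=1)
        assert fit.t_opt == pytest.approx(24.0, abs=0.1)
        assert fit.t_max == pytest.approx(28.0, abs=0.1)
        assert fit.mu_opt == pytest.approx(0.9, abs=0.01)

    def test_tmin_unconstrained_when_no_cold_data(self):
        truth = CardinalParams(-5.0, 24.0, 28.0, 0.9)
        temps = np.arange(10.0, 34.0)
        rates = make_rates(temps, [ctmi_mu(t, truth) for t in temps])
        fit = fit_ctmi(rates, seed=1)
        # Topt and Tmax recovered even though Tmin is unidentifiable
        assert fit.t_opt == pytest.approx(24.0, abs=0.5)
        assert fit.t_max == pytest.approx(28.0, abs=0.5)

    def test_scale_equivariance(self):
        rates = self.noiseless_rates()
        doubled = [
            RateMeasurement(r.strain, r.temperature, 2 * r.mu, r.stderr,
                            r.n_points, r.window)
            for r in rates
        ]
        f1, f2 = fit_ctmi(rates, seed=3), fit_ctmi(doubled, seed=3)
        assert f2.t_opt == pytest.approx(f1.t_opt, abs=0.05)
        assert f2.t_max == pytest.approx(f1.t_max, abs=0.05)
        assert f2.mu_opt == pytest.approx(2 * f1.mu_opt, rel=1e-3)

    def test_order_invariance_and_determinism(self, rng):
        rates = self.noiseless_rates()
        shuffled = [rates[i] for i in rng.permutation(len(rates))]
        f1, f2 = fit_ctmi(rates, seed=7), fit_ctmi(shuffled, seed=7)
        assert (f1.t_min, f1.t_opt, f1.t_max, f1.mu_opt) == (
            f2.t_min, f2.t_opt, f2.t_max, f2.mu_opt
        )

    def test_too_few_temperatures_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_ctmi(self.noiseless_rates(np.array([20.0, 22, 24, 26])))

    def test_all_zero_rates_unfittable(self):
        with pytest.raises(UnfittableError):
            fit_ctmi(make_rates(np.arange(10.0, 20.0), np.zeros(10)))

    def test_mixed_strains_rejected(self):
        rates = self.noiseless_rates()[:5] + make_rates([30.0], [0.1], strain="other")
        with pytest.raises(ValidationError):
            fit_ctmi(rates)


class TestBootstrapCI:
    TRUTH = CardinalParams(2.0, 24.0, 28.0, 0.9)

    def replicated_rates(self, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rates = []
        for t in np.arange(10.0, 34.0, 3.0):
            mu_true = ctmi_mu(t, self.TRUTH)
            for _ in range(3):
                rates.append(
                    RateMeasurement(
                        "s", float(t),
                        float(max(mu_true + rng.normal(0, sigma), 0.0)),
                        0.01, 8, (0.0, 7.0),
                    )
                )
        return rates

    def test_zero_replicates_invalid(self):
        with pytest.raises(ValidationError):
            ctmi_confidence_intervals(self.replicated_rates(), n_bootstrap=0)

    def test_noiseless_intervals_collapse(self):
        rates = self.replicated_rates(sigma=0.0)
        ci = ctmi_confidence_intervals(rates, n_bootstrap=50, seed=1)
        fit = fit_ctmi(rates, seed=1)
        assert ci["t_opt"][1] - ci["t_opt"][0] < 0.2
        assert ci["t_opt"][0] - 0.2 <= fit.t_opt <= ci["t_opt"][1] + 0.2

    def test_noisy_interval_brackets_truth(self):
        rates = self.replicated_rates(sigma=0.05, seed=3)
        ci = ctmi_confidence_intervals(rates, n_bootstrap=200, seed=3)
        lo, hi = ci["t_opt"]
        assert lo < 24.0 < hi
        assert hi - lo < 5.0
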