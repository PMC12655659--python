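"""Simulation engine: integration accuracy, steady-state machinery,
exposure metrics and Monte Carlo reproducibility."""

import numpy as np
import pytest

from radpk import (ConcentrationProfile, CovariateSampler, CovariateSet,
                   IndividualParams, exposure_metrics, monte_carlo_exposures,
                   simulate_profile, steady_state_window)
from radpk.engine import periodic_steady_state_window
from radpk.structural import typical_params


@pytest.fixture
def patient_params(theta, patient_cov):
    return typical_params(theta, patient_cov)


class TestSimulateProfile:
    def test_zero_doses_zero_profile(self, patient_params, theta):
        prof = simulate_profile(patient_params, theta, [],
                                np.arange(0.5, 24, 0.5))
        assert np.all(prof.conc == 0.0)

    def test_auc_equals_dose_over_cl_without_circadian(self, patient_params, theta):
        th0 = theta.replace(theta_circadian=0.0)
        grid = np.arange(0.25, 500.0, 0.25)
        prof = simulate_profile(patient_params, th0, [(0.0, 400.0)], grid)
        auc = np.trapezoid(prof.conc, prof.times)
        assert auc == pytest.approx(400.0 / 23.0 * 1000, rel=5e-3)

    def test_linearity_in_dose(self, patient_params, theta):
        grid = np.arange(0.5, 48, 0.5)
        c1 = simulate_profile(patient_params, theta, [(0.0, 300.0)], grid).conc
        c2 = simulate_profile(patient_params, theta, [(0.0, 600.0)], grid).conc
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-9)

    def test_rk4_agrees_with_adaptive_reference(self, patient_params, theta):
        grid = np.arange(0.5, 48.5, 0.5)
        doses = [(0.0, 300.0), (12.0, 300.0)]
        rk4 = simulate_profile(patient_params, theta, doses, grid).conc
        ivp = simulate_profile(patient_params, theta, doses, grid,
                               method="ivp").conc
        np.testing.assert_allclose(rk4, ivp, rtol=5e-4)

    def test_concentrations_non_negative(self, patient_params, theta):
        grid = np.arange(0.25, 336, 0.25)
        prof = simulate_profile(patient_params, theta,
                                [(24 * k, 300.0) for k in range(14)], grid)
        assert np.all(prof.conc >= 0)


class TestSteadyState:
    def test_superposition_oracle(self, patient_params, theta):
        """The steady-state window must match the superposition of
        single-dose profiles from the adaptive reference solver (the
        system is linear and, without the circadian term, autonomous)."""
        th0 = theta.replace(theta_circadian=0.0)
        tau, n_doses = 24.0, 30
        grid_rel = np.arange(0.25, 24.25, 0.25)
        single_grid = np.arange(0.25, tau * n_doses + 24.5, 0.25)
        single = simulate_profile(patient_params, th0, [(0.0, 400.0)],
                                  single_grid, method="ivp")
        superposed = np.zeros_like(grid_rel)
        t_win = (n_doses - 1) * tau
        for k in range(n_doses):
            td = t_win + grid_rel - k * tau
            superposed += np.interp(td, single.times, single.conc,
                                    left=0.0, right=0.0)
        window = steady_state_window(patient_params, th0, (400.0, 24.0),
                                     n_days=30)
        got = np.interp(grid_rel, window.times, window.conc)
        np.testing.assert_allclose(got, superposed, rtol=0.01)

    def test_one_compartment_trough_geometric_series(self, theta):
        """q = 0 reduction: trough from the closed-form geometric series
        of the one-compartment oral model with a fast transit chain."""
        th0 = theta.replace(theta_circadian=0.0)
        p = IndividualParams(cl=23.0, vc=383.0, q=0.0, vp=519.0, ka=1.59,
                             mtt=0.5, n_transit=1.0)
        tau = 24.0
        k = p.cl / p.vc
        ka, ktr = p.ka, (p.n_transit + 1) / p.mtt
        # residue expansion of depot->central with a 2-stage transit chain
        def single(t):
            t = np.asarray(t, float)
            out = np.zeros_like(t)
            pos = t > 0
            tp = t[pos]
            lams = np.array([k, ka, ktr])
            c = np.zeros_like(tp)
            # partial fractions of ktr^2*ka / ((s+ktr)^2 (s+ka)(s+k))
            A = ktr**2 * ka
            r_k = A / ((ktr - k) ** 2 * (ka - k))
            r_ka = A / ((ktr - ka) ** 2 * (k - ka))
            d1 = (ktr - ka) * (ktr - k)
            r_tr_lin = A / d1
            r_tr_const = A * ((ktr - ka) + (ktr - k)) / d1**2
            c = (r_k * np.exp(-k * tp) + r_ka * np.exp(-ka * tp)
                 + (r_tr_const + r_tr_lin * tp) * np.exp(-ktr * tp))
            out[pos] = c * 400.0 / p.vc * 1000
            return out
        troughs = single(tau * np.arange(1, 40))
        expected = troughs.sum()
        window = steady_state_window(p, th0, (400.0, 24.0), n_days=30)
        assert window.conc[-1] == pytest.approx(expected, rel=0.01)

    def test_window_auc_doubles_with_dose(self, patient_params, theta):
        w3 = steady_state_window(patient_params, theta, (300.0, 24.0))
        w6 = steady_state_window(patient_params, theta, (600.0, 24.0))
        np.testing.assert_allclose(w6.conc, 2 * w3.conc, rtol=1e-9)

    def test_window_starts_at_dose_time(self, patient_params, theta):
        w = steady_state_window(patient_params, theta, (300.0, 12.0))
        assert w.times[0] == 0.0
        assert w.times[-1] == pytest.approx(24.0)

    def test_periodic_solution_matches_brute_force(self, patient_params, theta):
        grid = np.arange(0.0, 24.25, 0.25)
        fast = periodic_steady_state_window(patient_params, theta,
                                            (300.0, 12.0), grid)
        brute = steady_state_window(patient_params, theta, (300.0, 12.0))
        np.testing.assert_allclose(fast, brute.conc, rtol=2e-3)

    def test_zero_circadian_ss_auc_is_daily_dose_over_cl(self, patient_params,
                                                         theta):
        th0 = theta.replace(theta_circadian=0.0)
        w = steady_state_window(patient_params, th0, (300.0, 12.0))
        auc = np.trapezoid(w.conc, w.times)
        assert auc == pytest.approx(600.0 / 23.0 * 1000, rel=0.01)


class TestExposureMetrics:
    def test_constant_profile(self):
        t = np.arange(0.0, 24.25, 0.25)
        m = exposure_metrics(ConcentrationProfile(t, np.full_like(t, 50.0)), 24.0)
        assert m.auc_0_24 == pytest.approx(1200.0)
        assert m.cmax == m.ctrough == 50.0

    def test_triangular_profile(self):
        t = np.arange(0.0, 24.25, 0.25)
        c = np.where(t <= 3, t / 3 * 100, (24 - t) / 21 * 100)
        m = exposure_metrics(ConcentrationProfile(t, c), 24.0)
        assert m.auc_0_24 == pytest.approx(1200.0, rel=1e-9)
        assert m.tmax == 3.0
        assert m.cmax == pytest.approx(100.0)
        assert m.ctrough == pytest.approx(0.0)

    def test_grid_refinement_invariance(self, patient_params, theta):
        coarse = steady_state_window(patient_params, theta, (300.0, 12.0),
                                     grid_dt=0.25)
        fine = steady_state_window(patient_params, theta, (300.0, 12.0),
                                   grid_dt=0.05)
        mc = exposure_metrics(coarse, 12.0)
        mf = exposure_metrics(fine, 12.0)
        assert mc.auc_0_24 == pytest.approx(mf.auc_0_24, rel=5e-3)
        assert mc.cmax == pytest.approx(mf.cmax, rel=5e-3)
        assert abs(mc.tmax - mf.tmax) <= 0.25

    def test_short_window_rejected(self):
        t = np.arange(0.0, 12.25, 0.25)
        with pytest.raises(ValueError):
            exposure_metrics(ConcentrationProfile(t, np.ones_like(t)), 12.0)


class TestMonteCarlo:
    def test_degenerate_population_medians_equal_typical(self, theta, variance):
        novar = variance.replace(omega_cl=0, omega_mtt=0, omega_n=0,
                                 omega_iov=0, sigma_prop=0)
        fixed_cov = CovariateSet(age=31, cml=1)
        sampler = lambda n, rng: [fixed_cov] * n
        summary = monte_carlo_exposures(theta, novar, sampler, (300.0, 12.0),
                                        20, seed=5, use_periodic_ss=True)
        typical = typical_params(theta, fixed_cov)
        grid = np.arange(0.0, 24.25, 0.25)
        conc = periodic_steady_state_window(typical, theta, (300.0, 12.0), grid)
        expected = exposure_metrics(ConcentrationProfile(grid, conc), 12.0)
        assert summary.summary.loc["auc_0_24", "median"] == pytest.approx(
            expected.auc_0_24, rel=1e-9)
        assert summary.summary.loc["cmax", "median"] == pytest.approx(
            expected.cmax, rel=1e-9)

    def test_seed_reproducibility(self, theta, variance):
        sampler = CovariateSampler()
        a = monte_carlo_exposures(theta, variance, sampler.patient,
                                  (400.0, 24.0), 50, seed=9,
                                  use_periodic_ss=True)
        b = monte_carlo_exposures(theta, variance, sampler.patient,
                                  (400.0, 24.0), 50, seed=9,
                                  use_periodic_ss=True)
        assert a.summary.equals(b.summary)

    def test_percentile_ordering(self, theta, variance):
        sampler = CovariateSampler()
        s = monte_carlo_exposures(theta, variance, sampler.patient,
                                  (300.0, 12.0), 50, seed=4,
                                  use_periodic_ss=True)
        for _, row in s.summary.iterrows():
            assert row.p05 <= row.q25 <= row["median"] <= row.q75 <= row.p95
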