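"""FOCE-I core: inner MAP problem, objective, oracle agreement and CWRES
contracts on analytic toy models (the full PK recovery experiment lives
in the acceptance suite)."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from radpk import PkModelSpec, PkProblem, cwres, fit
from radpk.estimation import foce_objective, foce_subject


def _toy_predict(t, D=100.0, V=10.0, k=0.3, scale=100.0):
    """One-compartment bolus with a log-normal eta on the elimination
    rate; returns a predict(eta) closure."""
    t = np.asarray(t, float)

    def predict(eta):
        ke = k * math.exp(eta[0]) if len(eta) else k
        return D / V * np.exp(-ke * t) * scale

    return predict


def _toy_data(seed, t, om=0.4, sig=0.2, **kw):
    rng = np.random.default_rng(seed)
    predict = _toy_predict(t, **kw)
    eta = rng.normal(0, om)
    y = predict([eta]) * (1 + rng.normal(0, sig, len(t)))
    return y, predict


def _quadrature_ofv(y, predict, om, sig):
    """-2 log marginal likelihood by adaptive quadrature, with the
    n*ln(2*pi) constant removed (matching the FOCE convention)."""

    def lik(e):
        f = predict([e])
        v = (sig * f) ** 2
        return math.exp(-0.5 * float(np.sum((y - f) ** 2 / v + np.log(2 * np.pi * v)))
                        - 0.5 * e * e / om / om) / math.sqrt(2 * math.pi) / om

    total, _ = quad(lik, -5 * om, 5 * om, limit=200)
    return -2.0 * math.log(total) - len(y) * math.log(2 * math.pi)


class TestInnerProblem:
    def test_map_matches_grid_search(self):
        t = np.array([1.0, 3.0, 8.0])
        y, predict = _toy_data(5, t)
        om, sig = 0.4, 0.2
        sf = foce_subject(y, predict, np.array([om]), sig)
        grid = np.linspace(-2, 2, 4001)

        def g(e):
            f = predict([e])
            v = (sig * f) ** 2
            return float(np.sum((y - f) ** 2 / v + np.log(v)) + e * e / om / om)

        best = grid[int(np.argmin([g(e) for e in grid]))]
        assert sf.eta_hat[0] == pytest.approx(best, abs=1e-3)

    def test_zero_iiv_forces_eta_to_zero_els(self):
        t = np.array([1.0, 4.0])
        y, predict = _toy_data(7, t)
        sig = 0.2
        sf = foce_subject(y, predict, np.zeros(0), sig)
        f = predict([])
        v = (sig * f) ** 2
        expected = float(np.sum((y - f) ** 2 / v + np.log(v)))
        assert sf.ofv == pytest.approx(expected, rel=1e-12)

    def test_single_observation_at_prediction(self):
        predict = lambda eta: np.array([1000.0 * math.exp(eta[0])]) \
            if len(eta) else np.array([1000.0])
        sf = foce_subject(np.array([1000.0]), predict, np.array([0.3]), 0.2)
        # near (not exactly at) the prior mean: the ln-variance term of
        # the interaction model shifts the mode by O(sigma^2)
        assert abs(sf.eta_hat[0]) < 0.05
        grid = np.linspace(-0.5, 0.5, 2001)

        def g(e):
            f = 1000.0 * math.exp(e)
            v = (0.2 * f) ** 2
            return (1000.0 - f) ** 2 / v + math.log(v) + e * e / 0.3 ** 2

        best = grid[int(np.argmin([g(e) for e in grid]))]
        assert sf.eta_hat[0] == pytest.approx(best, abs=2e-3)
        # with eta ~ 0, OFV ~ ln(sigma^2 f^2 + F^2 om^2)
        sf0 = foce_subject(np.array([1000.0]),
                           lambda e: np.array([1000.0]), np.zeros(0), 0.2)
        assert sf0.ofv == pytest.approx(math.log(0.2 ** 2 * 1000.0 ** 2))


class TestFoceVsQuadrature:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_ofv_within_two_percent_of_marginal(self, seed):
        t = np.array([0.5, 2.0, 6.0])
        om, sig = 0.4, 0.2
        y, predict = _toy_data(seed, t, om=om, sig=sig)
        sf = foce_subject(y, predict, np.array([om]), sig)
        exact = _quadrature_ofv(y, predict, om, sig)
        assert sf.ofv == pytest.approx(exact, rel=0.02)

    def test_multi_subject_objective_adds_contributions(self):
        t = np.array([1.0, 5.0])
        subs = []
        expect = 0.0
        for seed in (10, 11, 12):
            y, predict = _toy_data(seed, t)
            subs.append((y, predict, np.array([0.4])))
            expect += foce_subject(y, predict, np.array([0.4]), 0.2).ofv
        assert foce_objective(subs, 0.2) == pytest.approx(expect)

    def test_objective_invariant_to_subject_order(self):
        t = np.array([1.0, 5.0])
        subs = []
        for seed in (20, 21, 22):
            y, predict = _toy_data(seed, t)
            subs.append((y, predict, np.array([0.4])))
        assert foce_objective(subs, 0.2) == pytest.approx(
            foce_objective(subs[::-1], 0.2), rel=1e-9)


class TestCwres:
    def test_cwres_unit_scale_invariance(self):
        """Rescaling concentrations (unit change) leaves CWRES unchanged."""
        t = np.array([1.0, 3.0, 8.0])
        y, predict = _toy_data(33, t)
        sf1 = foce_subject(y, predict, np.array([0.4]), 0.2)
        scaled = _toy_predict(t, scale=100.0 * 1000)
        sf2 = foce_subject(y * 1000, scaled, np.array([0.4]), 0.2)
        np.testing.assert_allclose(sf1.cwres, sf2.cwres, atol=1e-5)

    def test_zero_noise_zero_iiv_cwres_is_zero(self):
        t = np.array([1.0, 3.0, 8.0])
        predict = _toy_predict(t)
        y = predict([])
        sf = foce_subject(y, predict, np.zeros(0), 0.2)
        np.testing.assert_allclose(sf.cwres, 0.0, atol=1e-12)


class TestFit:
    def test_all_fixed_returns_initial_ofv(self, theta, cl_only_variance,
                                           study_table_cl_only):
        problem = PkProblem(study_table_cl_only, h=0.1)
        spec = PkModelSpec(theta, cl_only_variance)
        res = fit(problem, spec, free=())
        assert res.n_fev == 1
        assert res.ofv == pytest.approx(problem.objective(spec))
        assert res.converged

    def test_noise_free_data_is_local_minimum(self, theta):
        """On a noise-free dataset generated at the initial values the
        OFV at the truth is below any perturbed clearance."""
        from radpk import generate_study
        from radpk.params import VarianceSpec
        novar = VarianceSpec(omega_cl=0, omega_mtt=0, omega_n=0,
                             omega_iov=0, sigma_prop=0.0)
        table = generate_study(theta, novar, seed=99)
        problem = PkProblem(table, h=0.1)
        # tiny sigma for a well-defined least-squares criterion
        eval_var = novar.replace(sigma_prop=0.05)
        ofv0 = problem.objective(PkModelSpec(theta, eval_var))
        for factor in (0.9, 1.1):
            spec = PkModelSpec(theta.replace(cl_pop=23.0 * factor), eval_var)
            assert problem.objective(spec) > ofv0

    def test_population_prediction_uses_zero_eta(self, theta,
                                                 cl_only_variance,
                                                 study_table_cl_only):
        """PRED in the GOF table equals the linearized population
        prediction f(eta_hat) - F eta_hat, which collapses onto the
        eta = 0 prediction when variability vanishes."""
        problem = PkProblem(study_table_cl_only, h=0.1)
        spec = PkModelSpec(theta, cl_only_variance.replace(omega_cl=1e-8))
        out = cwres(problem, spec)
        design = problem.subjects[0]
        names, _ = problem.eta_layout(spec.variance, design)
        pred0 = problem.predictor(spec, design, names)(np.zeros(1))
        got = out[out.ID == design.sid].PRED.to_numpy()
        np.testing.assert_allclose(got, pred0, rtol=1e-4)
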