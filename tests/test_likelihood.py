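"""Extended-Cox likelihood quantities and their analytic derivatives."""

import numpy as np
import pytest
from scipy.integrate import quad

from mplcox import (LikelihoodWorkspace, ParameterState, SubjectRecord,
                    SurvDataset, cum_hazard, hazard, log_likelihood,
                    penalised_loglik, psi_star, survival)
from mplcox.basis import make_basis
from tests.conftest import mixed_dataset


@pytest.fixture(scope="module")
def subject():
    return SubjectRecord(yL=2.0, yR=2.0, censor_type="event", x=[1.0, 0.3],
                         change_times=[0.0, 0.6, 1.4],
                         z_values=[[0.2], [-0.5], [0.9]])


@pytest.fixture(scope="module")
def basis():
    return make_basis([0.8, 1.6], (0.1, 3.0))


def random_params(basis, seed, p=2, q=1, lam=0.0):
    rng = np.random.default_rng(seed)
    return ParameterState(rng.normal(scale=0.4, size=p),
                          rng.normal(scale=0.4, size=q),
                          rng.uniform(0.1, 1.5, basis.m), lam=lam)


class TestPsiStar:
    def test_zero_gamma_telescopes_to_plain_cumulative(self, subject, basis):
        for t in [0.5, 1.2, 2.5]:
            np.testing.assert_allclose(psi_star(subject, basis, [0.0], t),
                                       basis.eval_cum(t), atol=1e-12)

    def test_zero_at_time_origin(self, subject, basis):
        assert np.all(psi_star(subject, basis, [0.7], 0.0) == 0)

    def test_matches_numerical_integration(self, subject, basis):
        gamma = np.array([0.7])
        t = 2.4
        a, b = basis.boundary
        ps = psi_star(subject, basis, gamma, t)
        for u in range(basis.m):
            def f(s):
                # psi_u has support [a, b]; the clamped point evaluation is
                # a boundary convention, not part of the integral
                if not a <= s <= b:
                    return 0.0
                return basis.eval(s)[u] * np.exp(
                    subject.covariate_at(s) @ gamma)
            val, _ = quad(f, 0.0, t, limit=400,
                          points=[a, 0.6, 1.4, 0.8, 1.6])
            assert abs(ps[u] - val) < 1e-7


class TestHazardQuantities:
    def test_baseline_reduction_and_zero_time(self, subject, basis):
        par = ParameterState([0.0, 0.0], [0.0], np.full(basis.m, 0.8))
        t = 1.7
        assert cum_hazard(subject, basis, par, t) == pytest.approx(
            0.8 * basis.eval_cum(t).sum())
        assert cum_hazard(subject, basis, par, 0.0) == 0.0
        assert hazard(subject, basis, par, t) == pytest.approx(
            0.8 * basis.eval(t).sum())

    def test_compositional_identity(self, subject, basis):
        par = random_params(basis, 2)
        for t in [0.4, 1.1, 2.6]:
            direct = cum_hazard(subject, basis, par, t)
            composed = float(np.exp(subject.x @ par.beta)
                             * (psi_star(subject, basis, par.gamma, t)
                                @ par.theta))
            assert direct == pytest.approx(composed)

    def test_zero_theta_gives_unit_survival(self, subject, basis):
        par = ParameterState([0.5, -0.2], [0.3], np.zeros(basis.m))
        assert hazard(subject, basis, par, 1.0) == 0.0
        assert survival(subject, basis, par, 2.0) == 1.0

    def test_hazard_is_log_derivative_of_survival(self, subject, basis):
        par = random_params(basis, 3)
        h = 1e-5
        for t in [0.9, 1.8, 2.3]:
            d = -(np.log(survival(subject, basis, par, t + h))
                  - np.log(survival(subject, basis, par, t - h))) / (2 * h)
            assert abs(d - hazard(subject, basis, par, t)) < 1e-4


class TestLogLikelihood:
    def test_single_right_censored_zero_hazard_mass(self, basis):
        s = SubjectRecord(yL=0.05, yR=np.inf, censor_type="right",
                          x=[0.0, 0.0], change_times=[0.0], z_values=[[0.0]])
        # basis support starts at 0.1, so H(0.05) = 0 and l = 0
        ds = SurvDataset(subjects=[s])
        par = ParameterState([0.0, 0.0], [0.0], np.full(basis.m, 1.0))
        assert log_likelihood(ds, basis, par) == 0.0

    def test_single_left_censored_plugin_value(self, basis):
        s = SubjectRecord(yL=0.0, yR=3.0, censor_type="left", x=[0.0, 0.0],
                          change_times=[0.0], z_values=[[0.0]])
        ds = SurvDataset(subjects=[s])
        # theta scaled so H(3.0) = sum_u theta_u * 1 = 1 -> S = e^{-1}
        par = ParameterState([0.0, 0.0], [0.0], np.full(basis.m, 1.0 / basis.m))
        assert log_likelihood(ds, basis, par) == pytest.approx(
            np.log(1 - np.exp(-1.0)), abs=1e-10)

    def test_mixed_dataset_matches_per_subject_oracle(self, basis):
        ds = mixed_dataset(n=16, seed=4)
        par = random_params(basis, 5)

        a, b = basis.boundary

        def H(subj, t):   # independent quadrature of the hazard
            def f(s):
                if not a <= s <= b:
                    return 0.0
                return float((basis.eval(s) @ par.theta)
                             * np.exp(subj.x @ par.beta
                                      + subj.covariate_at(s) @ par.gamma))
            val, _ = quad(f, 0.0, t, limit=500, points=[a])
            return val

        expected = 0.0
        for s in ds.subjects:
            if s.censor_type == "event":
                expected += (np.log(basis.eval(s.yL) @ par.theta)
                             + s.x @ par.beta
                             + s.covariate_at(s.yL) @ par.gamma - H(s, s.yL))
            elif s.censor_type == "right":
                expected += -H(s, s.yL)
            elif s.censor_type == "left":
                expected += np.log(1 - np.exp(-H(s, s.yR)))
            else:
                expected += np.log(np.exp(-H(s, s.yL)) - np.exp(-H(s, s.yR)))
        got = log_likelihood(ds, basis, par)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_invariant_to_repartitioning_constant_segments(self, basis):
        s1 = SubjectRecord(yL=1.0, yR=2.0, censor_type="interval",
                           x=[1.0, 0.0], change_times=[0.0, 1.5],
                           z_values=[[0.3], [0.8]])
        # split [0, 1.5) into two sub-intervals with the same z value
        s2 = SubjectRecord(yL=1.0, yR=2.0, censor_type="interval",
                           x=[1.0, 0.0], change_times=[0.0, 0.7, 1.5],
                           z_values=[[0.3], [0.3], [0.8]])
        par = random_params(basis, 6)
        l1 = log_likelihood(SurvDataset(subjects=[s1]), basis, par)
        l2 = log_likelihood(SurvDataset(subjects=[s2]), basis, par)
        assert l1 == pytest.approx(l2, abs=1e-12)


class TestPenalisedObjective:
    def test_reduces_to_loglik_without_smoothing(self, basis):
        ds = mixed_dataset(n=12, seed=9)
        par = random_params(basis, 7, lam=0.0)
        assert penalised_loglik(ds, basis, par) == log_likelihood(ds, basis, par)

    def test_never_exceeds_loglik_and_recomputes(self, basis):
        ds = mixed_dataset(n=12, seed=9)
        par = random_params(basis, 8, lam=0.9)
        phi = penalised_loglik(ds, basis, par)
        ll = log_likelihood(ds, basis, par)
        assert phi <= ll
        assert phi == pytest.approx(
            ll - 0.9 * par.theta @ basis.R @ par.theta, rel=1e-12)


class TestDerivatives:
    @pytest.mark.parametrize("lam", [0.0, 0.6])
    def test_score_matches_central_differences(self, basis, lam):
        ds = mixed_dataset(n=24, seed=2)
        ws = LikelihoodWorkspace(ds, basis)
        for seed in range(4):
            par = random_params(basis, 20 + seed, lam=lam)
            g = np.concatenate(ws.score(par))
            eta0 = par.eta
            h = 1e-6
            num = np.empty_like(g)
            for j in range(eta0.size):
                e = np.zeros_like(eta0)
                e[j] = h
                num[j] = (_phi(ws, eta0 + e, lam) - _phi(ws, eta0 - e, lam)) / (2 * h)
            np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-6)

    def test_hessian_matches_score_differences(self, basis):
        ds = mixed_dataset(n=24, seed=2)
        ws = LikelihoodWorkspace(ds, basis)
        par = random_params(basis, 31, lam=0.4)
        Hfull = ws.hessian(par)
        eta0 = par.eta
        h = 1e-5
        for j in range(eta0.size):
            e = np.zeros_like(eta0)
            e[j] = h
            col = (_score(ws, eta0 + e, 0.4) - _score(ws, eta0 - e, 0.4)) / (2 * h)
            np.testing.assert_allclose(Hfull[:, j], col, rtol=2e-4, atol=1e-5)

    def test_unpenalised_gradient_when_theta_interior_and_lam_zero(self, basis):
        ds = mixed_dataset(n=24, seed=2)
        ws = LikelihoodWorkspace(ds, basis)
        par = random_params(basis, 40, lam=0.0)
        pen = np.concatenate(ws.score(par, penalised=True))
        unpen = np.concatenate(ws.score(par, penalised=False))
        np.testing.assert_allclose(pen, unpen)

    def test_right_censored_curvature_equals_score_weights(self, basis):
        # with only events and right censoring, the beta-block score is
        # X'(delta - H) and its Hessian is -X' diag(H) X: the same
        # cumulative-hazard weights appear in both (A = C)
        ds = mixed_dataset(n=24, seed=13)
        keep = [s for s in ds.subjects if s.censor_type in ("event", "right")]
        ds = SurvDataset(subjects=keep)
        ws = LikelihoodWorkspace(ds, basis)
        par = random_params(basis, 41)
        Hvals = np.array([cum_hazard(s, basis, par, s.yL) for s in ds.subjects])
        delta = np.array([s.censor_type == "event" for s in ds.subjects],
                         dtype=float)
        g_b, _, _ = ws.score(par)
        np.testing.assert_allclose(g_b, ws.X.T @ (delta - Hvals), rtol=1e-10)
        np.testing.assert_allclose(ws.hessian_beta_block(par),
                                   -ws.X.T @ (Hvals[:, None] * ws.X),
                                   rtol=1e-10)


def _phi(ws, eta, lam):
    p, q = ws.p, ws.q
    par = ParameterState(eta[:p], eta[p:p + q],
                         np.maximum(eta[p + q:], 0.0), lam=lam)
    return ws.penalised(par)


def _score(ws, eta, lam):
    p, q = ws.p, ws.q
    par = ParameterState(eta[:p], eta[p:p + q],
                         np.maximum(eta[p + q:], 0.0), lam=lam)
    return np.concatenate(ws.score(par))
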