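"""Constrained Newton-MI optimisation: ascent, non-negativity, KKT."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from mplcox import (LikelihoodWorkspace, OptimizerConfig, ParameterState,
                    SubjectRecord, SurvDataset, build_basis, fit_inner)
from mplcox.newton_mi import (default_init, kkt_status, update_beta,
                              update_gamma, update_theta)
from tests.conftest import mixed_dataset

RTOL_PHI = 1e-9   # floating-point allowance on the ascent property


@pytest.fixture(scope="module")
def fitted():
    ds = mixed_dataset(n=48, seed=0)
    basis = build_basis(ds.observed_times(), ds.n0, m_override=5)
    ws = LikelihoodWorkspace(ds, basis)
    res = fit_inner(ws, config=OptimizerConfig(), lam=0.5)
    return ws, res


def test_converges_with_monotone_ascent(fitted):
    ws, res = fitted
    assert res.converged
    path = np.asarray(res.phi_path)
    tol = RTOL_PHI * (1.0 + np.abs(path[:-1]))
    assert np.all(np.diff(path) >= -tol)


def test_theta_nonnegative_throughout(fitted):
    _, res = fitted
    assert res.min_theta >= 0.0
    assert np.all(res.params.theta >= 0.0)


def test_kkt_certificate_reverified_independently(fitted):
    ws, res = fitted
    conf = OptimizerConfig()
    cert = kkt_status(ws, res.params, conf)
    assert cert["satisfied"]
    assert cert["grad_beta_sup"] < conf.kkt_tol
    assert cert["grad_gamma_sup"] < conf.kkt_tol
    g_t = cert["grad_theta"]
    for u, th in enumerate(res.params.theta):
        if th > conf.theta_floor:
            assert abs(g_t[u]) < conf.kkt_tol
        else:
            assert g_t[u] < conf.kkt_tol


def test_block_updates_fixed_at_stationary_point(fitted):
    ws, res = fitted
    conf = OptimizerConfig()
    st = res.params
    b2, _, _, _ = update_beta(st, ws, conf)
    g2, _, _, _ = update_gamma(st, ws, conf)
    t2, _, _, _ = update_theta(st, ws, conf)
    assert np.max(np.abs(b2.beta - st.beta)) < 1e-7
    assert np.max(np.abs(g2.gamma - st.gamma)) < 1e-7
    assert np.max(np.abs(t2.theta - st.theta)) < 1e-6


def _all_event_dataset(n=40, seed=8, q=1):
    rng = np.random.default_rng(seed)
    subs = []
    for _ in range(n):
        t = rng.uniform(0.2, 2.5)
        subs.append(SubjectRecord(
            yL=t, yR=t, censor_type="event", x=[float(rng.integers(0, 2))],
            change_times=[0.0], z_values=[[rng.normal(scale=0.5)]]))
    return SurvDataset(subjects=subs)


def test_beta_update_agrees_with_golden_section_oracle():
    # p = 1: iterated Newton beta steps must land on the 1-D maximiser of
    # Phi over beta found by direct scalar optimisation
    ds = _all_event_dataset()
    basis = build_basis(ds.observed_times(), ds.n0, m_override=4)
    ws = LikelihoodWorkspace(ds, basis)
    conf = OptimizerConfig()
    state = default_init(ws, lam=0.0)
    for _ in range(60):
        state, _, _, _ = update_beta(state, ws, conf)

    def neg_phi(b):
        return -ws.penalised(state.replace(beta=np.array([b])))
    opt = minimize_scalar(neg_phi, bounds=(-3.0, 3.0), method="bounded",
                          options={"xatol": 1e-10})
    assert abs(state.beta[0] - opt.x) < 1e-6


def test_gamma_update_agrees_with_golden_section_oracle():
    ds = _all_event_dataset(seed=15)
    basis = build_basis(ds.observed_times(), ds.n0, m_override=4)
    ws = LikelihoodWorkspace(ds, basis)
    conf = OptimizerConfig()
    state = default_init(ws, lam=0.0)
    for _ in range(60):
        state, _, _, _ = update_gamma(state, ws, conf)

    def neg_phi(g):
        return -ws.penalised(state.replace(gamma=np.array([g])))
    opt = minimize_scalar(neg_phi, bounds=(-3.0, 3.0), method="bounded",
                          options={"xatol": 1e-10})
    assert abs(state.gamma[0] - opt.x) < 1e-6


def test_null_model_recovers_zero_coefficients():
    # data generated with beta = gamma = 0: estimates should sit within
    # three standard errors of zero and satisfy the KKT conditions
    from mplcox.simulate import SimConfig, gen_study2_scenario1
    cfg = SimConfig(baseline="weibull", beta_true=(0.0, 0.0),
                    gamma_true=(0.0,), n=500, pi_E=0.7)
    ds = gen_study2_scenario1(cfg, seed=21)
    basis = build_basis(ds.observed_times(), ds.n0)
    ws = LikelihoodWorkspace(ds, basis)
    res = fit_inner(ws, config=OptimizerConfig(), lam=0.0)
    assert res.converged
    G = ws.neg_hessian_loglik(res.params)
    se = np.sqrt(np.diag(np.linalg.inv(G))[:3])
    est = np.concatenate([res.params.beta, res.params.gamma])
    assert np.all(np.abs(est) < 3.0 * se)


def test_subject_order_does_not_change_estimates():
    ds = mixed_dataset(n=40, seed=3)
    perm = np.random.default_rng(0).permutation(ds.n)
    ds_shuffled = SurvDataset(subjects=[ds.subjects[i] for i in perm])
    basis = build_basis(ds.observed_times(), ds.n0, m_override=5)
    r1 = fit_inner(LikelihoodWorkspace(ds, basis),
                   config=OptimizerConfig(), lam=0.3)
    r2 = fit_inner(LikelihoodWorkspace(ds_shuffled, basis),
                   config=OptimizerConfig(), lam=0.3)
    np.testing.assert_allclose(r1.params.eta, r2.params.eta, atol=1e-8)


def test_nonconvergence_is_flagged_not_raised():
    ds = mixed_dataset(n=40, seed=3)
    basis = build_basis(ds.observed_times(), ds.n0, m_override=5)
    res = fit_inner(LikelihoodWorkspace(ds, basis),
                    config=OptimizerConfig(max_iter=2), lam=0.3)
    assert not res.converged and res.iterations == 2


def test_invalid_optimizer_constants_rejected():
    with pytest.raises(ValueError):
        OptimizerConfig(armijo_shrink=1.5)
    with pytest.raises(ValueError):
        OptimizerConfig(kkt_tol=-1.0)
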