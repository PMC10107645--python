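"""Constrained maximisation of the penalised log-likelihood.

One outer iteration performs three alternating block updates, each with an
Armijo backtracking line search so the objective Phi never decreases:

1. Newton step on beta (time-fixed coefficients),
2. Newton step on gamma (time-varying coefficients),
3. multiplicative-iterative (MI) step on theta (spline coefficients).

The MI step rescales the theta gradient by theta_u / d_u, where d_u
accumulates the magnitudes of the negative-slope likelihood contributions
and the positive part of the penalty gradient (plus a small epsilon).  A
full step is then a multiplicative update theta_u * (positive part)/(d_u),
so the iterates stay non-negative; fractional steps are convex
combinations of the current point and that update, hence also
non-negative.  Components pinned at zero with negative gradients simply
stay at zero, which is exactly the Karush-Kuhn-Tucker (KKT) requirement
for an actively constrained maximiser.

Convergence is declared when the KKT conditions hold in sup-norm:
|dPhi/dbeta| and |dPhi/dgamma| below tolerance, and for each u either
theta_u is interior with |dPhi/dtheta_u| below tolerance, or theta_u is at
(numerically) zero with a non-ascending gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import (LikelihoodDegenerateError, LikelihoodWorkspace,
                         ParameterState)


@dataclass
class OptimizerConfig:
    """Knobs of the Newton-MI loop (defaults suit the simulated regimes)."""

    max_iter: int = 5000
    kkt_tol: float = 1e-6
    armijo_shrink: float = 0.5
    armijo_slope: float = 1e-2
    theta_floor: float = 1e-8   # below this, theta_u counts as boundary
    mi_eps: float = 1e-8        # denominator guard in the MI scaling
    ridge: float = 1e-8         # relative ridge for singular Newton blocks
    min_step: float = 1e-12
    # floating-point allowance in the sufficient-increase test: near the
    # optimum the predicted gain g'd/2|H| drops below the rounding noise of
    # Phi itself, and a strictly positive requirement would stall the search
    armijo_ftol: float = 4e-13

    def __post_init__(self):
        if not (0 < self.armijo_shrink < 1 and 0 < self.armijo_slope < 1):
            raise ValueError("Armijo constants must lie in (0, 1)")
        if min(self.max_iter, self.kkt_tol, self.theta_floor,
               self.mi_eps, self.min_step) <= 0:
            raise ValueError("optimizer constants must be positive")


@dataclass
class InnerResult:
    """Converged (or stalled) state of one fixed-lambda fit."""

    params: ParameterState
    converged: bool
    iterations: int
    phi: float
    kkt: dict = field(default_factory=dict)
    phi_path: list = field(default_factory=list)
    min_theta: float = np.inf   # smallest theta component seen at any iterate


def default_init(ws: LikelihoodWorkspace, lam: float = 0.0) -> ParameterState:
    """Scale-aware start: beta = gamma = 0, theta flat.

    theta is the constant making the implied H0 at the median finite
    observed time match the crude cumulative hazard -log(1 - f), where f is
    the non-right-censored fraction (clipped away from 0 and 1).
    """
    times = ws.dataset.observed_times()
    t_med = float(np.median(times))
    f = np.clip(ws.dataset.n0 / max(ws.n, 1), 0.05, 0.95)
    target = -np.log1p(-f)
    denom = float(np.sum(ws.basis.eval_cum(t_med)))
    theta0 = np.full(ws.m, target / max(denom, 1e-12))
    return ParameterState(np.zeros(ws.p), np.zeros(ws.q), theta0, lam=lam)


def _armijo(ws, params, cache, phi0, direction, block, slope, config):
    """Backtracking line search on Phi along `direction` in one block.

    Returns (new_params, new_cache, new_phi) or None when the search
    exhausts (step below min_step).
    """
    w = 1.0
    while w >= config.min_step:
        if block == "beta":
            cand = params.replace(beta=params.beta + w * direction)
        elif block == "gamma":
            cand = params.replace(gamma=params.gamma + w * direction)
        else:
            cand = params.replace(
                theta=np.maximum(params.theta + w * direction, 0.0))
        try:
            c = ws.compute(cand, reuse=cache, changed=block)
            phi = ws.penalised(cand, c)
        except LikelihoodDegenerateError:
            phi = -np.inf
        floor = config.armijo_ftol * (1.0 + abs(phi0))
        if np.isfinite(phi) and phi >= phi0 + config.armijo_slope * w * slope - floor:
            return cand, c, phi
        w *= config.armijo_shrink
    return None


def _newton_direction(Hblock, g, config):
    """Ascent direction from a (possibly ridged) Newton solve."""
    dim = g.size
    A = -Hblock
    tr = np.trace(A) / max(dim, 1)
    jitter = config.ridge * max(abs(tr), 1.0)
    for _ in range(8):
        try:
            d = np.linalg.solve(A + jitter * np.eye(dim), g)
        except np.linalg.LinAlgError:
            d = None
        if d is not None and g @ d > 0:
            return d
        jitter *= 100.0
    return g / max(abs(tr), 1.0)   # damped gradient fallback


def update_beta(state: ParameterState, ws: LikelihoodWorkspace,
                config: OptimizerConfig, cache=None, phi0=None):
    """One Newton/line-search step on beta; Phi never decreases."""
    if ws.p == 0:
        return state, cache, phi0, False
    cache = cache if cache is not None else ws.compute(state)
    phi0 = phi0 if phi0 is not None else ws.penalised(state, cache)
    g_b, _, _ = ws.score(state, cache)
    H_bb = ws.hessian_beta_block(state, cache)
    d = _newton_direction(H_bb, g_b, config)
    hit = _armijo(ws, state, cache, phi0, d, "beta", g_b @ d, config)
    if hit is None:
        return state, cache, phi0, True
    return hit[0], hit[1], hit[2], False


def update_gamma(state: ParameterState, ws: LikelihoodWorkspace,
                 config: OptimizerConfig, cache=None, phi0=None):
    """One Newton/line-search step on gamma; Phi never decreases."""
    if ws.q == 0:
        return state, cache, phi0, False
    cache = cache if cache is not None else ws.compute(state)
    phi0 = phi0 if phi0 is not None else ws.penalised(state, cache)
    _, g_g, _ = ws.score(state, cache)
    H_gg = ws.hessian_gamma_block(state, cache)
    d = _newton_direction(H_gg, g_g, config)
    hit = _armijo(ws, state, cache, phi0, d, "gamma", g_g @ d, config)
    if hit is None:
        return state, cache, phi0, True
    return hit[0], hit[1], hit[2], False


def update_theta(state: ParameterState, ws: LikelihoodWorkspace,
                 config: OptimizerConfig, cache=None, phi0=None):
    """One multiplicative-iterative step on theta; keeps theta >= 0."""
    cache = cache if cache is not None else ws.compute(state)
    phi0 = phi0 if phi0 is not None else ws.penalised(state, cache)
    grad, neg = ws.theta_grad_split(state, cache)
    scale = (state.theta + config.mi_eps) / (neg + config.mi_eps)
    d = scale * grad
    slope = grad @ d
    if slope <= 0:
        return state, cache, phi0, False
    hit = _armijo(ws, state, cache, phi0, d, "theta", slope, config)
    if hit is None:
        return state, cache, phi0, True
    return hit[0], hit[1], hit[2], False


def polish_theta(state: ParameterState, ws: LikelihoodWorkspace,
                 config: OptimizerConfig, cache=None, phi0=None):
    """Projected-Newton refinement of theta (tail-convergence accelerator).

    The MI step converges linearly, which is slow for components settling
    at tiny interior values or approaching the boundary.  This step solves
    the reduced Newton system on the free components (theta_u interior, or
    pinned at zero with an ascending gradient), projects the proposal onto
    theta >= 0 and Armijo-searches Phi, so the monotone-ascent and
    non-negativity guarantees of the main scheme are preserved; a rejected
    proposal leaves the MI iterate unchanged.
    """
    cache = cache if cache is not None else ws.compute(state)
    phi0 = phi0 if phi0 is not None else ws.penalised(state, cache)
    _, _, g_t = ws.score(state, cache)
    free = (state.theta > config.theta_floor) | (g_t > 0)
    if not np.any(free):
        return state, cache, phi0, False
    Htt = ws.hessian_theta_block(state, cache)[np.ix_(free, free)]
    d = np.zeros_like(state.theta)
    d[free] = _newton_direction(Htt, g_t[free], config)
    slope = g_t @ d
    if slope <= 0:
        return state, cache, phi0, False
    hit = _armijo(ws, state, cache, phi0, d, "theta", slope, config)
    if hit is None:
        return state, cache, phi0, True
    return hit[0], hit[1], hit[2], False


def kkt_status(ws: LikelihoodWorkspace, params: ParameterState,
               config: OptimizerConfig, cache=None) -> dict:
    """Independent KKT certificate at a candidate point."""
    cache = cache if cache is not None else ws.compute(params)
    g_b, g_g, g_t = ws.score(params, cache)
    tol = config.kkt_tol
    interior = params.theta > config.theta_floor
    theta_ok = np.where(interior, np.abs(g_t) < tol, g_t < tol)
    return {
        "grad_beta_sup": float(np.max(np.abs(g_b))) if g_b.size else 0.0,
        "grad_gamma_sup": float(np.max(np.abs(g_g))) if g_g.size else 0.0,
        "grad_theta": g_t,
        "satisfied": bool(
            (np.max(np.abs(g_b)) < tol if g_b.size else True)
            and (np.max(np.abs(g_g)) < tol if g_g.size else True)
            and np.all(theta_ok)),
    }


def fit_inner(data_or_ws, basis=None, init: ParameterState | None = None,
              config: OptimizerConfig | None = None,
              lam: float | None = None) -> InnerResult:
    """Maximise Phi at fixed lambda by the alternating Newton-MI scheme.

    Accepts either (dataset, basis) or a prebuilt LikelihoodWorkspace.
    Non-convergence within max_iter returns a flagged result, not an error.
    """
    ws = (data_or_ws if isinstance(data_or_ws, LikelihoodWorkspace)
          else LikelihoodWorkspace(data_or_ws, basis))
    config = config or OptimizerConfig()
    state = init if init is not None else default_init(ws)
    if lam is not None:
        state = state.replace(lam=lam)
    cache = ws.compute(state)
    phi = ws.penalised(state, cache)
    phi_path = [phi]
    min_theta = float(np.min(state.theta))
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        stalled = []
        state, cache, phi, s1 = update_beta(state, ws, config, cache, phi)
        state, cache, phi, s2 = update_gamma(state, ws, config, cache, phi)
        state, cache, phi, s3 = update_theta(state, ws, config, cache, phi)
        state, cache, phi, _ = polish_theta(state, ws, config, cache, phi)
        stalled = [s1, s2, s3]
        phi_path.append(phi)
        min_theta = min(min_theta, float(np.min(state.theta)))
        kkt = kkt_status(ws, state, config, cache)
        if kkt["satisfied"]:
            converged = True
            break
        if all(stalled):
            break   # no block can move; report as non-converged
    else:
        kkt = kkt_status(ws, state, config, cache)
    return InnerResult(params=state, converged=converged, iterations=it,
                       phi=phi, kkt=kkt, phi_path=phi_path,
                       min_theta=min_theta)
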