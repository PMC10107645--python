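"""Asymptotic inference for constrained MPL estimates.

Non-negativity constraints theta_u >= 0 that hold with equality at the
optimum ("active constraints") must be projected out before inverting the
information matrix — ignoring them can produce negative variances.  With U
the selection matrix dropping the r active components, the large-sample
covariance of eta_hat = (beta, gamma, theta) is the sandwich

    A^-1 = U [U' (G + lambda * H_J) U]^-1 U',
    var(eta_hat) = A^-1 G A^-1,

where G is the negative Hessian of the unpenalised log-likelihood and
H_J = blockdiag(0, 0, 2R) is the Hessian of the penalty J = theta'R theta.
Rows and columns of actively constrained components are exactly zero.

Survival predictions propagate the full covariance through
S(t) = exp(-H(t)) by the delta method on the eta scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import SplineBasis
from .data import SubjectRecord
from .likelihood import ParameterState, psi_star

Z975 = 1.959963984540054


def detect_active(theta, grad_theta, eps: float = 1e-2,
                  theta_tol: float = 1e-2) -> np.ndarray:
    """Indices of actively constrained components.

    u is active iff theta_u < theta_tol and the gradient of the penalised
    objective at u is below -eps (pressing against the boundary).
    """
    theta = np.asarray(theta, dtype=float)
    grad = np.asarray(grad_theta, dtype=float)
    return np.flatnonzero((theta < theta_tol) & (grad < -eps))


def sandwich_covariance(G: np.ndarray, lam: float, R: np.ndarray,
                        active: np.ndarray, p: int, q: int) -> np.ndarray:
    """Constrained sandwich covariance for eta = (beta, gamma, theta)."""
    d = G.shape[0]
    m = d - p - q
    HJ = np.zeros((d, d))
    HJ[p + q:, p + q:] = 2.0 * R
    keep = np.setdiff1d(np.arange(d), p + q + np.asarray(active, dtype=int))
    Mred = (G + lam * HJ)[np.ix_(keep, keep)]
    try:
        Minv = np.linalg.inv(Mred)
    except np.linalg.LinAlgError:
        warnings.warn("reduced information singular; adding ridge")
        jitter = 1e-8 * max(np.trace(Mred) / max(len(keep), 1), 1.0)
        Minv = np.linalg.inv(Mred + jitter * np.eye(len(keep)))
    Ainv = np.zeros((d, d))
    Ainv[np.ix_(keep, keep)] = Minv
    cov = Ainv @ G @ Ainv
    cov = 0.5 * (cov + cov.T)
    diag = np.diag(cov)[keep]
    if np.any(diag < -1e-10):
        raise RuntimeError(
            "negative variance in the sandwich covariance; re-check the "
            "active-constraint detection (components pressed against the "
            "boundary must be projected out)")
    return cov


@dataclass
class FitResult:
    """Converged MPL estimates with covariance and diagnostics."""

    params: ParameterState
    basis: SplineBasis
    covariance: np.ndarray
    active_set: np.ndarray
    nu: float
    sigma2: float
    converged: bool
    iterations: int
    loglik: float
    phi: float
    n: int
    p: int
    q: int
    outer_iterations: int = 0
    kkt: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    @property
    def lam(self) -> float:
        return self.params.lam

    @property
    def se(self) -> np.ndarray:
        """Standard errors for (beta, gamma, theta)."""
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    # -- summaries -------------------------------------------------------

    def summarise(self, names: list | None = None) -> pd.DataFrame:
        """Coefficient table (estimate, SE, z, p) for beta and gamma."""
        est = np.concatenate([self.params.beta, self.params.gamma])
        se = self.se[: self.p + self.q]
        if names is None:
            names = [f"x{j + 1}" for j in range(self.p)] + \
                    [f"z{b + 1}" for b in range(self.q)]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, est / se, np.nan)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({"estimate": est, "se": se, "z": z,
                             "p_value": pvals}, index=names)

    # -- baseline quantities ---------------------------------------------

    def baseline_hazard(self, times) -> np.ndarray:
        return np.atleast_2d(self.basis.eval(times)) @ self.params.theta

    def baseline_cum_hazard(self, times) -> np.ndarray:
        return np.atleast_2d(self.basis.eval_cum(times)) @ self.params.theta

    def baseline_survival(self, times, ci: bool = False):
        """S0(t) = exp(-theta' Psi(t)), optionally with delta-method 95% CI."""
        Psi = np.atleast_2d(self.basis.eval_cum(times))
        H0 = Psi @ self.params.theta
        S0 = np.exp(-H0)
        if not ci:
            return S0
        covT = self.covariance[self.p + self.q:, self.p + self.q:]
        var_H = np.einsum("tu,uv,tv->t", Psi, covT, Psi)
        sd_S = S0 * np.sqrt(np.clip(var_H, 0.0, None))
        lo = np.clip(S0 - Z975 * sd_S, 0.0, 1.0)
        hi = np.clip(S0 + Z975 * sd_S, 0.0, 1.0)
        return S0, sd_S, lo, hi


def summarise(fit: FitResult, names: list | None = None) -> pd.DataFrame:
    return fit.summarise(names)


def _profile_subject(x, change_times, z_values) -> SubjectRecord:
    """Wrap a covariate profile as a pseudo-subject for prediction."""
    return SubjectRecord(yL=1.0, yR=1.0, censor_type="event",
                         x=np.atleast_1d(np.asarray(x, dtype=float)),
                         change_times=change_times, z_values=z_values)


def _eta_gradient_of_H(fit: FitResult, subject: SubjectRecord, t: float):
    """(H(t), dH/deta) for the delta method."""
    params = fit.params
    ps = psi_star(subject, fit.basis, params.gamma, t)
    exb = float(np.exp(subject.x @ params.beta))
    H = exb * float(ps @ params.theta)
    dH_beta = subject.x * H
    # gamma: per-segment hazard mass times segment covariate value
    ct = subject.change_times
    ends = np.append(ct[1:], np.inf)
    starts = np.minimum(ct, t)
    stops = np.minimum(ends, t)
    keep = stops > starts
    dH_gamma = np.zeros(params.gamma.size)
    if np.any(keep):
        dPsi = fit.basis.eval_cum(stops[keep]) - fit.basis.eval_cum(starts[keep])
        w = np.exp(subject.z_values[keep] @ params.gamma)
        mass = w * (dPsi @ params.theta)
        dH_gamma = exb * (mass @ subject.z_values[keep])
    dH_theta = exb * ps
    return H, np.concatenate([dH_beta, dH_gamma, dH_theta])


def predict_survival(fit: FitResult, x, change_times, z_values,
                     times) -> pd.DataFrame:
    """Predicted survival curve with point-wise delta-method 95% CI.

    The covariate profile is a time-fixed vector x plus a piecewise-
    constant trajectory (change_times starting at 0, one row of z_values
    per constancy interval).  Times beyond the basis interval are clamped.
    """
    subject = _profile_subject(x, change_times, z_values)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    S = np.empty(times.size)
    sd = np.empty(times.size)
    for j, t in enumerate(times):
        if t <= 0:
            S[j], sd[j] = 1.0, 0.0
            continue
        H, gradH = _eta_gradient_of_H(fit, subject, t)
        Sj = np.exp(-H)
        var_H = float(gradH @ fit.covariance @ gradH)
        S[j] = Sj
        sd[j] = Sj * np.sqrt(max(var_H, 0.0))
    lo = np.clip(S - Z975 * sd, 0.0, 1.0)
    hi = np.clip(S + Z975 * sd, 0.0, 1.0)
    return pd.DataFrame({"time": times, "survival": S, "se": sd,
                         "lo95": lo, "hi95": hi})
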