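"""Penalised log-likelihood for the extended Cox model and its derivatives.

Model: subject i has hazard

    h_i(t) = h0(t) * exp(x_i' beta + z_i(t)' gamma),
    h0(t)  = sum_u theta_u psi_u(t),  theta_u >= 0,

with z_i piecewise constant between change times.  The cumulative hazard
then telescopes over the constancy segments,

    H_i(t) = exp(x_i' beta) * sum_u theta_u PsiStar_ui(t),
    PsiStar_ui(t) = sum_a [Psi_u(min(t, t_{a+1})) - Psi_u(min(t, t_a))]
                    * exp(z_ia' gamma),

and with S_i = exp(-H_i) the partly-interval-censored log-likelihood is

    l = sum_i  delta_i [ln h0(y_i) + x_i'beta + z_i(y_i)'gamma - H_i(y_i)]
             - delta_iR H_i(y_iL)
             + delta_iL ln(1 - S_i(y_iR))
             + delta_iI ln(S_i(y_iL) - S_i(y_iR)).

The penalised objective is Phi = l - lambda * theta' R theta.

Derivatives are organised around per-subject *evaluation points*: each
subject contributes its likelihood through H at one time (event, right,
left) or two times (interval).  Writing w_k = dl_i/dH(t_k) and
w_kl = d2 l_i / dH(t_k) dH(t_l), every score and Hessian block is a
weighted sum of dH/d(parameter) terms; the weights per censoring type are
closed-form functions of S at the evaluation points (see
docs/derivations.md).  All segment-level spline quantities are
precomputed once per (dataset, basis) pair in `LikelihoodWorkspace`, so
repeated evaluation during optimisation touches only small dense and
sparse matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .basis import SplineBasis
from .data import SubjectRecord, SurvDataset

_DIFF_FLOOR = 1e-300  # floor on S(yL) - S(yR) before taking the log


class LikelihoodDegenerateError(FloatingPointError):
    """The likelihood is -inf or non-finite at the requested parameters."""


@dataclass
class ParameterState:
    """Model parameters eta = (beta, gamma, theta) plus smoothing value."""

    beta: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray
    lam: float = 0.0

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if np.any(self.theta < 0):
            raise ValueError("theta must be elementwise non-negative")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    @property
    def eta(self) -> np.ndarray:
        return np.concatenate([self.beta, self.gamma, self.theta])

    def replace(self, **kw) -> "ParameterState":
        d = {"beta": self.beta, "gamma": self.gamma,
             "theta": self.theta, "lam": self.lam}
        d.update(kw)
        return ParameterState(**d)


# ---------------------------------------------------------------------------
# direct (per-subject) quantities: used for prediction and as building blocks
# ---------------------------------------------------------------------------

def psi_star(subject: SubjectRecord, basis: SplineBasis, gamma, t: float) -> np.ndarray:
    """PsiStar_u(t): segment-wise covariate-weighted cumulative basis."""
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    ct = subject.change_times
    ends = np.append(ct[1:], np.inf)
    starts = np.minimum(ct, t)
    stops = np.minimum(ends, t)
    keep = stops > starts
    if not np.any(keep):
        return np.zeros(basis.m)
    dPsi = basis.eval_cum(stops[keep]) - basis.eval_cum(starts[keep])
    w = np.exp(subject.z_values[keep] @ gamma)
    return w @ dPsi


def cum_hazard(subject: SubjectRecord, basis: SplineBasis,
               params: ParameterState, t: float) -> float:
    """H_i(t) = exp(x'beta) * theta' PsiStar(t)."""
    ps = psi_star(subject, basis, params.gamma, t)
    return float(np.exp(subject.x @ params.beta) * (ps @ params.theta))


def hazard(subject: SubjectRecord, basis: SplineBasis,
           params: ParameterState, t: float) -> float:
    """h_i(t) = h0(t) exp(x'beta + z(t)'gamma)."""
    h0 = float(basis.eval(t) @ params.theta)
    lin = float(subject.x @ params.beta + subject.covariate_at(t) @ params.gamma)
    return h0 * np.exp(lin)


def survival(subject: SubjectRecord, basis: SplineBasis,
             params: ParameterState, t: float) -> float:
    """S_i(t) = exp(-H_i(t))."""
    return float(np.exp(-cum_hazard(subject, basis, params, t)))


# ---------------------------------------------------------------------------
# workspace: precomputed spline/segment structures for one (dataset, basis)
# ---------------------------------------------------------------------------

class LikelihoodWorkspace:
    """Precomputed design structures for fast repeated likelihood evaluation.

    Evaluation points (K of them, one or two per subject) hold H; segment
    rows (M of them) hold the per-constancy-interval increments of the
    cumulative basis clipped at the evaluation time.
    """

    def __init__(self, dataset: SurvDataset, basis: SplineBasis):
        self.dataset = dataset
        self.basis = basis
        n = dataset.n
        self.n, self.p, self.q, self.m = n, dataset.p, dataset.q, basis.m

        self.X = np.array([s.x for s in dataset.subjects], dtype=float).reshape(n, self.p)
        ctypes = np.array([s.censor_type for s in dataset.subjects])
        self.is_event = ctypes == "event"
        self.is_right = ctypes == "right"
        self.is_left = ctypes == "left"
        self.is_interval = ctypes == "interval"
        self.delta = self.is_event.astype(float)

        # evaluation points
        pt_subj, pt_time = [], []
        pt_event, pt_right, pt_left, pt_intL, pt_intR = [], [], [], [], []
        for i, s in enumerate(dataset.subjects):
            if s.censor_type == "event":
                pt_event.append(len(pt_subj)); pt_subj.append(i); pt_time.append(s.yL)
            elif s.censor_type == "right":
                pt_right.append(len(pt_subj)); pt_subj.append(i); pt_time.append(s.yL)
            elif s.censor_type == "left":
                pt_left.append(len(pt_subj)); pt_subj.append(i); pt_time.append(s.yR)
            else:
                pt_intL.append(len(pt_subj)); pt_subj.append(i); pt_time.append(s.yL)
                pt_intR.append(len(pt_subj)); pt_subj.append(i); pt_time.append(s.yR)
        self.pt_subj = np.asarray(pt_subj, dtype=int)
        self.pt_time = np.asarray(pt_time, dtype=float)
        self.K = len(pt_subj)
        self.pt_event = np.asarray(pt_event, dtype=int)
        self.pt_right = np.asarray(pt_right, dtype=int)
        self.pt_left = np.asarray(pt_left, dtype=int)
        self.pt_intL = np.asarray(pt_intL, dtype=int)
        self.pt_intR = np.asarray(pt_intR, dtype=int)

        # segment rows: for each point k, the subject's constancy intervals
        # clipped at t_k
        row_pt, row_start, row_stop, row_z = [], [], [], []
        for k in range(self.K):
            s = dataset.subjects[self.pt_subj[k]]
            tk = self.pt_time[k]
            ct = s.change_times
            ends = np.append(ct[1:], np.inf)
            for a in range(s.ni):
                if ct[a] >= tk:
                    break
                row_pt.append(k)
                row_start.append(ct[a])
                row_stop.append(min(ends[a], tk))
                row_z.append(s.z_values[a])
        self.row_pt = np.asarray(row_pt, dtype=int)
        self.M = len(row_pt)
        self.row_z = (np.asarray(row_z, dtype=float).reshape(self.M, self.q)
                      if self.M else np.empty((0, self.q)))
        starts = np.asarray(row_start, dtype=float)
        stops = np.asarray(row_stop, dtype=float)
        both = np.concatenate([stops, starts])
        cums = basis.eval_cum(both) if self.M else np.empty((0, self.m))
        self.row_dPsi = cums[: self.M] - cums[self.M:]
        # point <- row aggregation matrix
        self.agg = sp.csr_matrix(
            (np.ones(self.M), (self.row_pt, np.arange(self.M))),
            shape=(self.K, self.M))
        self.row_exb_idx = self.pt_subj[self.row_pt]

        # event-specific design pieces
        ev_sub = [dataset.subjects[self.pt_subj[k]] for k in self.pt_event]
        ev_t = self.pt_time[self.pt_event]
        self.psi_y = (basis.eval(ev_t).reshape(len(ev_sub), self.m)
                      if len(ev_sub) else np.empty((0, self.m)))
        self.z_at_y = (np.array([s.covariate_at(t) for s, t in zip(ev_sub, ev_t)],
                                dtype=float).reshape(len(ev_sub), self.q)
                       if len(ev_sub) else np.empty((0, self.q)))
        self.x_event = self.X[self.pt_subj[self.pt_event]]
        self.ev_subj = self.pt_subj[self.pt_event]

    # -- parameter-dependent cache --------------------------------------

    def compute(self, params: ParameterState, reuse: dict | None = None,
                changed: str | None = None) -> dict:
        """Evaluate all H-related quantities at the given parameters.

        When a single block moved since `reuse` was computed, pass
        ``changed`` in {'beta', 'gamma', 'theta'} to skip the unaffected
        pipeline stages (the optimiser's line searches live here).
        """
        beta, gamma, theta = params.beta, params.gamma, params.theta
        if reuse is not None and changed == "beta":
            exb = np.exp(self.X @ beta)
            w_seg, wdPsi = reuse["w_seg"], reuse["wdPsi"]
            PsiStar, H0s, h0y = reuse["PsiStar"], reuse["H0s"], reuse["h0y"]
        elif reuse is not None and changed == "theta":
            exb, w_seg, wdPsi = reuse["exb"], reuse["w_seg"], reuse["wdPsi"]
            PsiStar = reuse["PsiStar"]
            H0s = PsiStar @ theta
            h0y = self.psi_y @ theta
        else:
            exb = (reuse["exb"] if reuse is not None and changed == "gamma"
                   else np.exp(self.X @ beta))
            w_seg = np.exp(self.row_z @ gamma)
            wdPsi = w_seg[:, None] * self.row_dPsi
            PsiStar = self.agg @ wdPsi                   # (K, m)
            H0s = PsiStar @ theta
            h0y = self.psi_y @ theta                     # (ne,)
        H = exb[self.pt_subj] * H0s
        return {
            "exb": exb, "w_seg": w_seg, "wdPsi": wdPsi,
            "PsiStar": PsiStar, "H0s": H0s, "H": H, "h0y": h0y,
            "S": np.exp(-H),
        }

    def _weights(self, c):
        """First/second-order likelihood weights per evaluation point."""
        H, S = c["H"], c["S"]
        w1 = np.zeros(self.K)
        w2d = np.zeros(self.K)
        w1[self.pt_event] = -1.0
        w1[self.pt_right] = -1.0
        iL = self.pt_left
        if iL.size:
            Sl = S[iL]
            om = -np.expm1(-H[iL])            # 1 - S, stable for small H
            om = np.maximum(om, _DIFF_FLOOR)
            # H == 0 can occur exactly when yR sits at the basis boundary:
            # the contribution is then a parameter-free constant (dH/deta
            # = 0) and the 1/om weights would otherwise produce inf * 0
            ok = H[iL] > 0
            om = np.where(ok, om, 1.0)
            w1[iL] = np.where(ok, Sl / om, 0.0)
            w2d[iL] = np.where(ok, -Sl / np.square(om), 0.0)
        kL, kR = self.pt_intL, self.pt_intR
        w2x = np.zeros(kL.size)
        if kL.size:
            SL, SR = S[kL], S[kR]
            D = np.maximum(SL - SR, _DIFF_FLOOR)
            w1[kL] = -SL / D
            w1[kR] = SR / D
            prod = SL * SR / D ** 2
            w2d[kL] = -prod
            w2d[kR] = -prod
            w2x = prod
        return w1, w2d, w2x

    # -- objective -------------------------------------------------------

    def loglik(self, params: ParameterState, c=None) -> float:
        c = c or self.compute(params)
        H, h0y = c["H"], c["h0y"]
        ll = 0.0
        if self.pt_event.size:
            if np.any(h0y <= 0):
                raise LikelihoodDegenerateError(
                    "baseline hazard is zero at an observed event time")
            lin = self.x_event @ params.beta + self.z_at_y @ params.gamma
            ll += float(np.sum(np.log(h0y) + lin - H[self.pt_event]))
        if self.pt_right.size:
            ll -= float(np.sum(H[self.pt_right]))
        if self.pt_left.size:
            om = np.maximum(-np.expm1(-H[self.pt_left]), _DIFF_FLOOR)
            ll += float(np.sum(np.log(om)))
        if self.pt_intL.size:
            D = np.maximum(c["S"][self.pt_intL] - c["S"][self.pt_intR],
                           _DIFF_FLOOR)
            ll += float(np.sum(np.log(D)))
        if not np.isfinite(ll):
            raise LikelihoodDegenerateError("non-finite log-likelihood")
        return ll

    def penalised(self, params: ParameterState, c=None) -> float:
        pen = params.lam * float(params.theta @ (self.basis.R @ params.theta))
        return self.loglik(params, c) - pen

    # -- score -----------------------------------------------------------

    def score(self, params: ParameterState, c=None, penalised=True):
        """Gradient of Phi (or of l if penalised=False): (g_beta, g_gamma, g_theta)."""
        c = c or self.compute(params)
        w1, _, _ = self._weights(c)
        H, exb, PsiStar = c["H"], c["exb"], c["PsiStar"]
        # beta
        u = np.bincount(self.pt_subj, weights=w1 * H, minlength=self.n)
        g_beta = self.X.T @ (self.delta + u)
        # gamma: dH/dgamma per point
        mass_row = c["w_seg"] * (self.row_dPsi @ params.theta)
        dHdg = (self.agg @ (mass_row[:, None] * self.row_z)) \
            * exb[self.pt_subj][:, None]                  # (K, q)
        g_gamma = self.z_at_y.sum(axis=0) + dHdg.T @ w1
        # theta: dH/dtheta per point
        ePsi = exb[self.pt_subj][:, None] * PsiStar       # (K, m)
        g_theta = ePsi.T @ w1
        if self.pt_event.size:
            h0y = c["h0y"]
            if np.any(h0y <= 0):
                raise LikelihoodDegenerateError(
                    "baseline hazard is zero at an observed event time")
            g_theta = g_theta + self.psi_y.T @ (1.0 / h0y)
        if penalised and params.lam > 0:
            g_theta = g_theta - 2.0 * params.lam * (self.basis.R @ params.theta)
        c["dHdg"], c["ePsi"], c["mass_row"] = dHdg, ePsi, mass_row
        return g_beta, g_gamma, g_theta

    def theta_grad_split(self, params: ParameterState, c=None):
        """Positive/negative decomposition of dPhi/dtheta for the MI step.

        Returns (grad, denom_neg) where denom_neg collects the magnitudes of
        the negative-slope contributions (plus the positive part of the
        penalty gradient), the standard multiplicative-iterative scaling.
        """
        c = c or self.compute(params)
        w1, _, _ = self._weights(c)
        exb, PsiStar = c["exb"], c["PsiStar"]
        ePsi = exb[self.pt_subj][:, None] * PsiStar
        wneg = np.where(w1 < 0, -w1, 0.0)
        neg = ePsi.T @ wneg
        grad = ePsi.T @ w1
        if self.pt_event.size:
            grad = grad + self.psi_y.T @ (1.0 / c["h0y"])
        if params.lam > 0:
            pgrad = 2.0 * params.lam * (self.basis.R @ params.theta)
            grad = grad - pgrad
            neg = neg + np.maximum(pgrad, 0.0)
        return grad, neg

    # -- Hessian ---------------------------------------------------------

    def hessian_beta_block(self, params: ParameterState, c=None) -> np.ndarray:
        """The (p, p) Hessian block of Phi alone (cheap; no theta terms)."""
        c = c or self.compute(params)
        w1, w2d, w2x = self._weights(c)
        H = c["H"]
        coef = np.bincount(self.pt_subj, weights=w1 * H + w2d * H * H,
                           minlength=self.n)
        kL, kR = self.pt_intL, self.pt_intR
        if kL.size:
            coef += np.bincount(self.pt_subj[kL],
                                weights=2.0 * w2x * H[kL] * H[kR],
                                minlength=self.n)
        return self.X.T @ (coef[:, None] * self.X)

    def hessian_gamma_block(self, params: ParameterState, c=None) -> np.ndarray:
        """The (q, q) Hessian block of Phi alone."""
        c = c or self.compute(params)
        w1, w2d, w2x = self._weights(c)
        exb = c["exb"]
        mass_row = c["w_seg"] * (self.row_dPsi @ params.theta)
        dHdg = (self.agg @ (mass_row[:, None] * self.row_z)) \
            * exb[self.pt_subj][:, None]
        row_w = w1[self.row_pt] * exb[self.row_exb_idx]
        Hgg = self.row_z.T @ ((row_w * mass_row)[:, None] * self.row_z)
        Hgg += dHdg.T @ (w2d[:, None] * dHdg)
        kL, kR = self.pt_intL, self.pt_intR
        if kL.size:
            cross = dHdg[kL].T @ (w2x[:, None] * dHdg[kR])
            Hgg += cross + cross.T
        return Hgg

    def hessian_theta_block(self, params: ParameterState, c=None,
                            penalised=True) -> np.ndarray:
        """The (m, m) Hessian block of Phi (or l) alone."""
        c = c or self.compute(params)
        w1, w2d, w2x = self._weights(c)
        exb = c["exb"]
        ePsi = exb[self.pt_subj][:, None] * c["PsiStar"]
        Htt = ePsi.T @ (w2d[:, None] * ePsi)
        kL, kR = self.pt_intL, self.pt_intR
        if kL.size:
            cross = ePsi[kL].T @ (w2x[:, None] * ePsi[kR])
            Htt += cross + cross.T
        if self.pt_event.size:
            h0y = c["h0y"]
            Htt -= self.psi_y.T @ ((1.0 / h0y ** 2)[:, None] * self.psi_y)
        if penalised and params.lam > 0:
            Htt = Htt - 2.0 * params.lam * self.basis.R
        return Htt

    def hessian(self, params: ParameterState, c=None, penalised=True):
        """Full analytic Hessian of Phi (or l) as one (p+q+m)^2 matrix."""
        c = c or self.compute(params)
        if "dHdg" not in c:
            self.score(params, c)
        w1, w2d, w2x = self._weights(c)
        H, exb = c["H"], c["exb"]
        dHdg, ePsi, mass_row = c["dHdg"], c["ePsi"], c["mass_row"]
        kL, kR = self.pt_intL, self.pt_intR
        p, q, m, n = self.p, self.q, self.m, self.n

        # beta-beta: X' diag(coef) X
        coef = np.bincount(self.pt_subj, weights=w1 * H + w2d * H * H,
                           minlength=n)
        if kL.size:
            coef += np.bincount(self.pt_subj[kL],
                                weights=2.0 * w2x * H[kL] * H[kR], minlength=n)
        H_bb = self.X.T @ (coef[:, None] * self.X)

        row_w = w1[self.row_pt] * exb[self.row_exb_idx]
        # gamma-gamma
        rz = self.row_z
        H_gg = rz.T @ ((row_w * mass_row)[:, None] * rz)
        H_gg += dHdg.T @ (w2d[:, None] * dHdg)
        if kL.size:
            vL, vR = dHdg[kL], dHdg[kR]
            cross = vL.T @ (w2x[:, None] * vR)
            H_gg += cross + cross.T

        # theta-theta
        H_tt = ePsi.T @ (w2d[:, None] * ePsi)
        if kL.size:
            eL, eR = ePsi[kL], ePsi[kR]
            cross = eL.T @ (w2x[:, None] * eR)
            H_tt += cross + cross.T
        if self.pt_event.size:
            h0y = c["h0y"]
            H_tt -= self.psi_y.T @ ((1.0 / h0y ** 2)[:, None] * self.psi_y)

        # beta-gamma and beta-theta: accumulate per-subject vectors
        acc_g = w1[:, None] * dHdg + (w2d * H)[:, None] * dHdg
        acc_t = w1[:, None] * ePsi + (w2d * H)[:, None] * ePsi
        if kL.size:
            np.add.at(acc_g, kL, (w2x * H[kL])[:, None] * dHdg[kR])
            np.add.at(acc_g, kR, (w2x * H[kR])[:, None] * dHdg[kL])
            np.add.at(acc_t, kL, (w2x * H[kL])[:, None] * ePsi[kR])
            np.add.at(acc_t, kR, (w2x * H[kR])[:, None] * ePsi[kL])
        Sg = np.zeros((n, q))
        St = np.zeros((n, m))
        np.add.at(Sg, self.pt_subj, acc_g)
        np.add.at(St, self.pt_subj, acc_t)
        H_bg = self.X.T @ Sg
        H_bt = self.X.T @ St

        # gamma-theta
        H_gt = rz.T @ ((row_w * c["w_seg"])[:, None] * self.row_dPsi)
        H_gt += dHdg.T @ (w2d[:, None] * ePsi)
        if kL.size:
            H_gt += dHdg[kL].T @ (w2x[:, None] * ePsi[kR])
            H_gt += dHdg[kR].T @ (w2x[:, None] * ePsi[kL])

        full = np.zeros((p + q + m, p + q + m))
        full[:p, :p] = H_bb
        full[:p, p:p + q] = H_bg
        full[p:p + q, :p] = H_bg.T
        full[:p, p + q:] = H_bt
        full[p + q:, :p] = H_bt.T
        full[p:p + q, p:p + q] = H_gg
        full[p:p + q, p + q:] = H_gt
        full[p + q:, p:p + q] = H_gt.T
        full[p + q:, p + q:] = H_tt
        if penalised and params.lam > 0:
            full[p + q:, p + q:] -= 2.0 * params.lam * self.basis.R
        return full

    def hessian_blocks(self, params: ParameterState, c=None):
        """Negative-curvature blocks for the Newton steps on beta and gamma."""
        full = self.hessian(params, c)
        p, q = self.p, self.q
        return full[:p, :p], full[p:p + q, p:p + q]

    def neg_hessian_loglik(self, params: ParameterState) -> np.ndarray:
        """G: negative Hessian of the *unpenalised* log-likelihood."""
        return -self.hessian(params, penalised=False)


# ---------------------------------------------------------------------------
# module-level convenience wrappers
# ---------------------------------------------------------------------------

def log_likelihood(data: SurvDataset, basis: SplineBasis,
                   params: ParameterState,
                   ws: LikelihoodWorkspace | None = None) -> float:
    ws = ws or LikelihoodWorkspace(data, basis)
    return ws.loglik(params)


def penalised_loglik(data: SurvDataset, basis: SplineBasis,
                     params: ParameterState,
                     ws: LikelihoodWorkspace | None = None) -> float:
    ws = ws or LikelihoodWorkspace(data, basis)
    return ws.penalised(params)


def score(data: SurvDataset, basis: SplineBasis, params: ParameterState,
          ws: LikelihoodWorkspace | None = None, penalised: bool = True):
    ws = ws or LikelihoodWorkspace(data, basis)
    return ws.score(params, penalised=penalised)


def hessian(data: SurvDataset, basis: SplineBasis, params: ParameterState,
            ws: LikelihoodWorkspace | None = None, penalised: bool = True):
    ws = ws or LikelihoodWorkspace(data, basis)
    return ws.hessian(params, penalised=penalised)
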