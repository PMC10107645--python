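# Score and Hessian derivations

The log-likelihood of one subject depends on the parameters only through
the cumulative hazard evaluated at one or two times (and, for events,
through $h_0$ and the linear predictor at the event time).  This note
records the weight calculus used by `LikelihoodWorkspace` and how each
block is assembled.  Everything here is validated in the test suite
against central-difference numerics at random parameter points on data
containing all four censoring types.

## Cumulative-hazard building blocks

With the covariate-constancy segments $[t_a, t_{a+1})$ of subject $i$
and $\Delta\Psi_{u,a}(t) = \Psi_u(\min(t, t_{a+1})) - \Psi_u(\min(t, t_a))$:

$$H(t) = e^{x^\top\beta} \sum_a e^{z_a^\top\gamma}\,
         \theta^\top \Delta\Psi_a(t).$$

Its parameter gradients (all exact finite sums):

* $\partial H/\partial\beta = x\,H$,
* $\partial H/\partial\gamma = e^{x^\top\beta}\sum_a m_a(t)\, z_a$ with the
  segment hazard mass $m_a(t) = e^{z_a^\top\gamma}\,\theta^\top\Delta\Psi_a(t)$,
* $\partial H/\partial\theta_u = e^{x^\top\beta}\,\Psi^{*}_u(t)$ where
  $\Psi^{*}_u(t) = \sum_a e^{z_a^\top\gamma}\Delta\Psi_{u,a}(t)$.

Second derivatives of $H$: $\partial^2 H/\partial\beta\partial\beta^\top
= x x^\top H$; $\partial^2 H/\partial\gamma\partial\gamma^\top =
e^{x^\top\beta}\sum_a m_a z_a z_a^\top$;
$\partial^2 H/\partial\gamma\partial\theta_u =
e^{x^\top\beta}\sum_a e^{z_a^\top\gamma}\Delta\Psi_{u,a}\, z_a$;
$\partial^2 H/\partial\theta\partial\theta^\top = 0$; and the mixed
$\beta$ blocks are $x$ times the corresponding first derivatives.

## Likelihood weights per censoring type

Write $w_k = \partial \ell_i/\partial H(t_k)$ and
$w_{kl} = \partial^2 \ell_i/\partial H(t_k)\partial H(t_l)$, with
$S = e^{-H}$:

| type | evaluation point(s) | $w$ | second order |
|---|---|---|---|
| event at $y$ | $y$ | $-1$ | $0$ |
| right at $y_L$ | $y_L$ | $-1$ | $0$ |
| left at $y_R$ | $y_R$ | $S/(1-S)$ | $-S/(1-S)^2$ |
| interval | $y_L, y_R$ | $-S_L/D,\ +S_R/D$ | $\mp S_L S_R/D^2$ (diagonal $-$, cross $+$), $D = S_L - S_R$ |

The event term additionally contributes
$\partial/\partial\theta_u\,[\ln h_0(y)] = \psi_u(y)/h_0(y)$ (with second
derivative $-\psi_u\psi_v/h_0^2$) and the linear terms $x$, $z(y)$ to the
$\beta$, $\gamma$ scores.

Every score entry is then $\sum_k w_k\,\partial H_k/\partial\eta$ plus the
event extras, and every Hessian block is
$\sum_k w_k\,\partial^2 H_k/\partial\eta\partial\eta^\top
+ \sum_{k,l} w_{kl}\,(\partial H_k/\partial\eta)(\partial H_l/\partial\eta)^\top$,
where the double sum couples the two evaluation points of interval
subjects only.  The penalty adds $-2\lambda R\theta$ to the $\theta$
score and $-2\lambda R$ to the $\theta$ block.

## Special cases

* **Events and right censoring only.**  All second-order weights vanish,
  so the $\beta$ score is $X^\top(\delta - H)$ and its Hessian
  $-X^\top\mathrm{diag}(H)X$: the same per-subject cumulative-hazard
  weights appear in the gradient and the curvature (asserted as a test).
* **MI split.**  The $\theta$ gradient of $\ell$ separates into
  non-negative contributions (event $\psi_u/h_0$ terms and points with
  $w_k > 0$: left points and interval right endpoints) and non-positive
  ones ($w_k < 0$: event, right, interval left endpoints).  The MI
  denominator is the magnitude sum of the negative part plus
  $[2\lambda R\theta]^+$, giving the non-negativity-preserving
  multiplicative form of the update.

## Implementation notes

All $\Delta\Psi$ arrays depend only on the data and basis and are
precomputed once; a sparse point-by-segment incidence matrix turns the
per-segment quantities into per-evaluation-point sums, so one likelihood
or derivative evaluation is a handful of small dense/sparse products.
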