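# Methods

## Model

For subject $i$ with time-fixed covariates $x_i \in \mathbb{R}^p$ and
piecewise-constant time-varying covariates $z_i(t) \in \mathbb{R}^q$, the
hazard is the extended Cox model

$$h_i(t) = h_0(t)\,e^{x_i^\top\beta + z_i(t)^\top\gamma},$$

with the baseline hazard expanded in $m$ cubic M-splines,
$h_0(t) = \sum_u \theta_u \psi_u(t)$, $\theta_u \ge 0$.  M-splines are
non-negative with local support and unit integral over the basis interval
$[a,b]$; their running integrals (I-splines) are non-decreasing with
$\Psi_u(a)=0$, so $H_0$ is automatically a valid cumulative hazard for any
non-negative $\theta$.  $[a,b]$ spans the minimum and maximum finite
positive observed interval endpoints; $m$ follows the cube-root guideline
$m = \max(\mathrm{order}, \operatorname{round}(n_0^{1/3}))$ with $n_0$ the
non-right-censored count, and the $m-4$ interior knots sit at equally
spaced quantiles of the observed times.  Quantile placement adapts knot
density to where the data carry information; the number of knots, not
their exact placement, dominates behaviour, and the penalty further
reduces sensitivity to both.

Observations are partly interval censored: each subject contributes an
exact event time, a right-censoring time, a left-censoring time, or an
interval $[y_L, y_R]$, under independent (non-informative) censoring.
With $S_i = e^{-H_i}$ the log-likelihood is the standard four-term sum
(event density, right survivor, left CDF, interval probability mass).
Because $z_i$ is piecewise constant, $H_i(t)$ telescopes over the
covariate-constancy segments, which makes likelihood, score and Hessian
exact finite sums — no quadrature enters the fit.

The penalised objective is $\Phi = \ell - \lambda\,\theta^\top R\,\theta$
with the curvature penalty $r_{uv} = \int \psi_u''\psi_v''\,dt$, computed
exactly by per-segment two-point Gauss–Legendre (the integrand is
piecewise quadratic for cubics).

## Constrained optimisation

$\Phi$ is maximised subject to $\theta \ge 0$ by alternating block
updates, each safeguarded by Armijo backtracking so $\Phi$ never
decreases:

1. Newton step on $\beta$ using the analytic $(p,p)$ Hessian block;
2. Newton step on $\gamma$ using the analytic $(q,q)$ block;
3. a multiplicative-iterative (MI) step on $\theta$: the gradient is
   rescaled by $\theta_u / d_u$, where $d_u$ collects the magnitudes of
   the negative-slope likelihood contributions plus the positive part of
   the penalty gradient (plus $\varepsilon = 10^{-8}$).  A full step is a
   multiplicative update, so the iterates remain non-negative; fractional
   steps are convex combinations and inherit the property.

Derivatives are organised around per-subject evaluation points (one for
event/right/left, two for interval subjects): writing
$w_k = \partial \ell_i / \partial H(t_k)$ and the corresponding second
derivatives, every score/Hessian block reduces to weighted sums of
$\partial H/\partial\eta$ terms with closed-form weights per censoring
type (docs/derivations.md gives the expressions and how they were
validated against numerical differentiation).

Two numerical decisions matter in practice:

* **Projected-Newton polish on $\theta$.**  The MI step converges
  linearly and crawls for components settling at tiny values, so after
  each MI step a reduced Newton direction on the free components is
  tried, projected onto $\theta \ge 0$, and accepted only if the Armijo
  test passes.  This preserves monotone ascent and non-negativity while
  giving quadratic tail convergence; without it a sup-norm gradient
  tolerance of $10^{-6}$ is unreachable in thousands of iterations.
* **Floating-point allowance in the line search.**  Near the optimum the
  predicted gain $g^\top d$ falls below the rounding noise of $\Phi$
  itself ($\sim 10^{-13}|\Phi|$); the sufficient-increase test therefore
  carries an absolute allowance of $4\times10^{-13}(1+|\Phi|)$, without
  which the search stalls with gradients pinned near $10^{-6}$.

Convergence is the KKT certificate in sup-norm: free-parameter gradients
below `kkt_tol` (default $10^{-6}$), and each $\theta_u$ either interior
with $|g_u| <$ tol or at (numerically) zero with $g_u <$ tol.
Degenerate inputs: an all-right-censored dataset is rejected (no
information on the baseline scale); an event time where $h_0 = 0$ raises
a likelihood-degeneracy error; the interval probability mass
$S(y_L)-S(y_R)$ is floored at $10^{-300}$ so early iterates far from the
optimum keep a finite objective; a left-censored $y_R$ at the basis
boundary has $H \equiv 0$ and contributes a parameter-free constant,
handled by zeroing its weights.

## Smoothing selection

The penalty corresponds to the improper normal prior
$\theta \sim N(0, \sigma^2 R^{-1})$, $\sigma^2 = 1/(2\lambda)$.  Laplace
approximation of the marginal likelihood of $\sigma^2$ gives the
fixed-point update
$\sigma^2 \leftarrow \theta^\top R\,\theta / (m-\nu)$ with
$\nu = \operatorname{tr}\{(G+Q)^{-1}Q\}$, $Q$ holding $R/\sigma^2$ in the
$\theta$ block and $G$ the negative Hessian of the unpenalised
log-likelihood at the current estimates; $m-\nu$ acts as the model
degrees of freedom.  The driver:

* seeds $\sigma^2$ at its $\lambda \to 0$ limit
  $\theta^\top R\,\theta/m$ (where $\nu = 0$) from a pilot unpenalised
  fit — an initialisation on the light-smoothing side of the fixed
  point;
* alternates full inner fits (warm-started) with the update, stopping
  when consecutive $\nu$ values differ by less than 1 (outer cap 20);
* floors $\sigma^2$ at $1/(20n)$, i.e. caps $\lambda$ at $10n$: when the
  data are content with a penalty-null (affine) baseline the fixed point
  collapses to $\sigma^2 = 0$, while the asymptotics require
  $\lambda \ll n$; $\nu$ is clipped to $[0, m)$ since $G$ can be
  indefinite at boundary points of $\theta \ge 0$.

The coarse $\nu$-stabilisation rule deliberately stops short of exact
fixed-point convergence.  Running the update to its exact fixed point
selects visibly heavier smoothing and measurably attenuates the
time-varying coefficient on partly-interval-censored data; the
early-stopped rule is the published procedure and is what the simulation
results characterise.

## Inference

Active constraints ($\hat\theta_u < 10^{-2}$ with penalised gradient
below $-10^{-2}$) are projected out through a selection matrix $U$; the
covariance of $\hat\eta$ is the constrained sandwich
$A^{-1} G A^{-1}$ with
$A^{-1} = U[U^\top(G + 2\lambda R^{\mathrm{full}})U]^{-1}U^\top$, where
$R^{\mathrm{full}}$ embeds $R$ in the $\theta$ block (the penalty Hessian
is $2R$).  Rows/columns of active components are exactly zero.  Ignoring
active constraints can make variances negative; that condition is
detected and raised.  With no active set and $\lambda = 0$ the sandwich
collapses to the inverse observed information.

Predicted survival $S = e^{-H}$ for a covariate profile propagates the
full $(\beta,\gamma,\theta)$ covariance by the delta method on the
$\eta$ scale ($\partial S/\partial\eta = -S\,\partial H/\partial\eta$,
with the analytic segment-sum gradient of $H$); pointwise 95% intervals
are truncated to $[0,1]$.  The delta-method standard errors were checked
against a 2000-draw parametric bootstrap from
$N(\hat\eta, \widehat{\mathrm{var}})$ (within 15% on a moderate fit).

## Synthetic data

The generators emulate two study designs around four closed-form
baseline hazards (Gompertz $0.5e^{0.2t}$; "exponential-label" $h_0(t)=t$,
i.e. $H_0 = t^2/2$, implemented exactly as written; Weibull $3t^2$;
log-logistic $4.5t/(1+t^2)$).  Event times come from inversion:
$T = H_i^{-1}(-\log U)$, solved segment-by-segment in closed form for
piecewise-constant covariates and by bracketing plus adaptive quadrature
for the continuous sinusoid $z(t) = \tau_i\sin 2t$, $\tau_i\sim N(1,1)$.

* **Study 1** (right censoring): $X_1\sim\mathrm{Bern}(0.5)$,
  $X_2\sim U[0,1]$, a single $0\to1$ jump in $Z_1$ at
  $V \sim U[\tau_1,\tau_2]$, true $\beta=(1,-0.5)$, $\gamma_1=-1$;
  censoring $C\sim U[b_1,b_2]$.
* **Study 2 Scenario 1** (partly-interval): with probability $\pi_E$ the
  exact time is kept; otherwise the pair
  $(\alpha_L U_L,\ \alpha_R U_R)$ classifies the subject as left,
  interval or right censored.
* **Study 2 Scenario 2** (interval only): event status is assessed on a
  per-subject schedule (Poisson-many visits, mean 6, zero counts
  redrawn; $U[\tau_1,\tau_2]$ gaps), so every time is left-, interval-
  or right-censored.  Covariate change times are treated as known
  (the model's stated observation scheme); only Condition 3's continuous
  covariate is discretised onto the visit grid for fitting while the
  exact sinusoid drives generation.

The designs leave the window constants free, so they are calibrated once
per regime by a $10^4$-draw Monte-Carlo pre-run on a fixed internal
stream (independent of user seeds, so all replicates share the same
constants): $b_2$ solves $P(T<C)=\pi_E$ by bisection;
$\alpha_L/\alpha_R = 0.5/1.5\times$ the median latent event time; the
change-time window $[0, \mathrm{median}(T)]$ makes the $Z_1=0/1$
person-time roughly balanced; Scenario-2 visit gaps span
$[\text{median}/8, \text{median}/2]$ so a mean-6 schedule covers the
bulk of the event-time distribution with non-trivial left and right
censoring.  Generated datasets are validated by construction and every
inversion satisfies $|H_i(T)+\log U| < 10^{-8}$.

What the generators do **not** emulate: covariate measurement error,
informative censoring or assessment schedules, ties from coarse
recording, truncation, competing risks.  Passing tests therefore speak
to the estimator under clean independent censoring with correctly
recorded trajectories, not to robustness against those violations.

## Replicated studies and problem sizes

`run_simulation_study` aggregates per-replicate estimates into bias,
mean asymptotic SE next to the Monte-Carlo SD, and 95% coverage (both
asymptotic Wald and Monte-Carlo-SE intervals; the latter is the form
quoted for baseline survival when a comparator offers no asymptotic SE).
Non-converged replicates are excluded and counted.  Replicated runs use
a throughput optimiser profile (`kkt_tol = 1e-4`, `max_iter = 1000`);
estimates are insensitive to tightening beyond this, which was chosen as
the package's standard study profile.  The bundled reproduction script
uses 500 replicates at $n=200$ regimes, 150 for the schedule-censored
regime, and 100 at $n=1000$.

## Known limitations

* The baseline hazard is estimated on $[a,b]$ only; predictions clamp
  beyond $b$ (flat $H_0$), so extrapolated survival is conservative.
* The marginal-likelihood smoothing level depends on the early-stopped
  $\nu$ rule; fully converging the fixed point yields smoother baselines
  and more attenuated time-varying coefficients in small samples.
* Time-varying *coefficients* $\beta(t)$, truncation, and joint
  longitudinal-survival modelling are out of scope.
* The continuous-covariate path is approximated by its values at
  assessment times when fitting; fine schedules make this accurate, very
  sparse ones do not.
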