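"""Fit the MPL extended Cox model to partly-interval-censored data.

Simulates a cohort in which 70% of subjects have exact event times and
the rest are left-, interval- or right-censored, with one binary
time-varying covariate that can switch on during follow-up, then fits the
penalised-likelihood model with automatic smoothing selection.
"""

import numpy as np

from mplcox import fit, gen_study2_scenario1, make_preset

config = make_preset("s2s1-weibull", n=300, pi_E=0.7)
data = gen_study2_scenario1(config, seed=7)
print("censoring pattern:", data.censor_counts())

result = fit(data)
print("\ncoefficients (true beta = (1, -0.5), gamma1 = -1):")
print(result.summarise().round(4).to_string())
print(f"\nselected smoothing lambda = {result.lam:.4g} "
      f"(sigma^2 = {result.sigma2:.4g}, nu = {result.nu:.2f})")
print(f"basis: m = {result.basis.m} cubic M-splines on "
      f"[{result.basis.boundary[0]:.3f}, {result.basis.boundary[1]:.3f}]")

# baseline survival against the simulation truth S0(t) = exp(-t^3)
times = np.array([0.5, 0.75, 1.0, 1.25])
S0, sd, lo, hi = result.baseline_survival(times, ci=True)
print("\nbaseline survival (truth exp(-t^3)):")
for t, s, l, h in zip(times, S0, lo, hi):
    print(f"  t={t:4.2f}  S0_hat={s:.3f} [{l:.3f}, {h:.3f}]  "
          f"truth={np.exp(-t**3):.3f}")
# Each estimate should track the truth within its 95% interval; the
# coefficient table's z and p columns test each covariate effect against 0.
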