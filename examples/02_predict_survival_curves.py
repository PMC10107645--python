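"""Predicted survival for covariate profiles, with delta-method CIs.

Compares two subjects who differ only in whether (and when) a binary
time-varying exposure switches on — e.g. a treatment introduced mid
follow-up — using the fitted covariance of all parameters to propagate
uncertainty into point-wise 95% confidence bands.
"""

import numpy as np

from mplcox import fit, gen_study2_scenario1, make_preset, predict_survival

data = gen_study2_scenario1(make_preset("s2s1-weibull", n=300, pi_E=0.7),
                            seed=7)
result = fit(data)

times = np.linspace(0.0, 1.3, 14)
x = [1.0, 0.5]                                   # time-fixed profile
never = predict_survival(result, x, [0.0], [[0.0]], times)
early = predict_survival(result, x, [0.0, 0.3], [[0.0], [1.0]], times)

print("survival, never exposed vs exposed from t=0.3 (gamma1 < 0 means the")
print("exposure lowers the hazard, so the exposed curve sits higher):\n")
print(f"{'t':>5} {'S_never [95% CI]':>24} {'S_exposed [95% CI]':>24}")
for i, t in enumerate(times):
    print(f"{t:5.2f} {never['survival'][i]:8.3f} "
          f"[{never['lo95'][i]:.3f}, {never['hi95'][i]:.3f}]   "
          f"{early['survival'][i]:8.3f} "
          f"[{early['lo95'][i]:.3f}, {early['hi95'][i]:.3f}]")
# The two curves coincide until the exposure time 0.3 and then separate;
# non-overlapping bands at a time point indicate a clear difference there.
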