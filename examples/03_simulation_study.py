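"""A miniature replicated simulation study.

Repeatedly simulates partly-interval-censored cohorts, fits the model,
and tabulates bias, the agreement between asymptotic (sandwich) and
Monte-Carlo standard errors, and 95% confidence-interval coverage —
the same summaries used to validate the estimator at scale.
"""

from mplcox import make_preset
from mplcox.study import run_simulation_study, study_optimizer_config

config = make_preset("s2s1-weibull", n=200, pi_E=0.7)
res = run_simulation_study(config, n_reps=40, seed=11,
                           opt=study_optimizer_config())

print(f"{res.n_reps} replicates, {res.n_excluded} excluded "
      f"(non-converged)\n")
print(res.table.round(4).to_string())
print("""
Reading the table: `bias` is the mean deviation of the estimate from the
generating truth; `se_asymptotic` (mean sandwich SE) should track `se_mc`
(SD of the estimates across replicates); `cp` is the fraction of nominal
95% Wald intervals covering the truth, and `cp_mc` the same using the
Monte-Carlo SE.  S0_t1..t3 are the baseline survival estimates at the
true 25/50/75% percentile times.  At 40 replicates the coverage entries
carry a binomial error of about +/-0.07.""")
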