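"""Synthetic trial to parameter recovery.

Simulates a two-arm randomized trial (250 patients per arm, multinomial
90-day mRS outcomes, binomial sICH) at the base-case truth, estimates the
per-category risk ratios with 95% CIs, splices them into the parameter set
and re-runs the base case -- showing how sampling noise in a trial of this
size propagates into the ICER.
"""

from strokecea import evaluate, load_parameters
from strokecea.trial import simulate_trial, trial_to_parameters

params = load_parameters()
truth = evaluate(params)

trial = simulate_trial(params.base_mrs, params.risk_ratios,
                       n_per_arm=250, seed=7,
                       p_sich_std=params.config.p_sich_std,
                       p_sich_tnk=params.config.p_sich_tnk)
print("observed mRS counts (standard):    ", trial.counts_std.tolist())
print("observed mRS counts (tenecteplase):", trial.counts_tnk.tolist())
print("estimated risk ratios:", [f"{x:.2f}" for x in trial.rr_point])

fitted = trial_to_parameters(trial, params)
refit = evaluate(fitted)
print(f"truth-driven ICER: {truth.icer:,.0f} CNY/QALY")
print(f"trial-driven ICER: {refit.icer:,.0f} CNY/QALY")
print()
print("Interpretation: a single 250/arm trial estimates the risk ratios "
      "with wide CIs, so the plug-in ICER scatters around the truth; "
      "repeating this across seeds quantifies that sampling variability.")
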