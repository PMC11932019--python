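# Base-case model inputs for the tenecteplase-vs-standard-care cost-utility
# model (Chinese healthcare-system perspective).
#
# All monetary values are 2023 CNY. All event rates are annualized; the engine
# converts them to 3-month cycle probabilities internally. Ranges are the
# published plausible ranges / 95% intervals used for one-way and probabilistic
# sensitivity analysis; `dist` names the sampling family used in PSA.

# --- 90-day mRS distribution under standard treatment (multinomial block) ---
mrs3mo_std_0: {value: 0.067, range: [0.036, 0.098], dist: dirichlet}
mrs3mo_std_1: {value: 0.175, range: [0.128, 0.221], dist: dirichlet}
mrs3mo_std_2: {value: 0.091, range: [0.056, 0.127], dist: dirichlet}
mrs3mo_std_3: {value: 0.234, range: [0.182, 0.286], dist: dirichlet}
mrs3mo_std_4: {value: 0.226, range: [0.175, 0.278], dist: dirichlet}
mrs3mo_std_5: {value: 0.075, range: [0.043, 0.108], dist: dirichlet}
mrs3mo_std_6: {value: 0.131, range: [0.089, 0.173], dist: dirichlet}

# --- Per-category risk ratios, tenecteplase vs standard, 90-day mRS ---
rr_mrs0: {value: 1.46, range: [0.81, 2.62], dist: lognormal}
rr_mrs1: {value: 1.32, range: [0.94, 1.87], dist: lognormal}
rr_mrs2: {value: 1.16, range: [0.69, 1.96], dist: lognormal}
rr_mrs3: {value: 0.74, range: [0.53, 1.05], dist: lognormal}
rr_mrs4: {value: 0.95, range: [0.69, 1.32], dist: lognormal}
rr_mrs5: {value: 0.55, range: [0.27, 1.14], dist: lognormal}
rr_mrs6: {value: 1.01, range: [0.65, 1.58], dist: lognormal}

# --- Acute-phase event probabilities ---
p_sich_tnk: {value: 0.019, range: [0.003, 0.035], dist: beta}
p_sich_std: {value: 0.008, range: [0.0, 0.019], dist: beta}

# --- Long-term epidemiology (annual unless stated) ---
annual_recurrence: {value: 0.112, range: [0.096, 0.128], dist: beta}
# Conditional probability of death per recurrent-stroke event (not annualized).
p_death_after_recurrence: {value: 0.21, range: [0.189, 0.232], dist: beta}

# Hazard ratios for non-stroke (background) mortality by mRS state.
hr_mrs0: {value: 1.0, range: [1.0, 1.2], dist: lognormal}
hr_mrs1: {value: 1.0, range: [1.0, 1.2], dist: lognormal}
hr_mrs2: {value: 1.11, range: [1.0, 1.3], dist: lognormal}
hr_mrs3: {value: 1.27, range: [1.02, 1.52], dist: lognormal}
hr_mrs4: {value: 1.71, range: [1.37, 2.05], dist: lognormal}
hr_mrs5: {value: 2.37, range: [1.9, 2.84], dist: lognormal}

# Annual background mortality probability by age band (China, general
# population). The last band is open-ended; ages below the first band reuse
# its value.
background_mortality:
  - [67, 69, 0.01266]
  - [70, 74, 0.02159]
  - [75, 79, 0.03731]
  - [80, 84, 0.0634]
  - [85, null, 0.1512]

# --- Utilities (per year) ---
u_mrs0: {value: 0.95, range: [0.94, 0.96], dist: beta}
u_mrs1: {value: 0.89, range: [0.87, 0.96], dist: beta}
u_mrs2: {value: 0.67, range: [0.54, 0.83], dist: beta}
u_mrs3: {value: 0.44, range: [0.29, 0.60], dist: beta}
u_mrs4: {value: 0.16, range: [0.09, 0.23], dist: beta}
u_mrs5: {value: 0.1, range: [0.0, 0.21], dist: beta}
u_recurrence: {value: 0.42, range: [0.11, 0.71], dist: beta}
d_sich: {value: 0.38, range: [0.30, 0.46], dist: beta}

# --- Costs (2023 CNY) ---
cost_tnk_per_mg: {value: 230.5, range: [115.0, 459.4], dist: gamma}
cost_acute_mrs01: {value: 12472.0, range: [7204.0, 15704.0], dist: gamma}
cost_acute_mrs25: {value: 16490.0, range: [9063.0, 21624.0], dist: gamma}
cost_acute_death: {value: 14133.0, range: [6640.0, 18679.0], dist: gamma}
cost_sich: {value: 3012.0, range: [654.0, 6285.0], dist: gamma}
cost_posthosp_mrs01: {value: 8867.0, range: [2655.0, 11311.0], dist: gamma}
cost_posthosp_mrs25: {value: 13492.0, range: [3393.0, 16968.0], dist: gamma}
cost_recurrent_stroke: {value: 18380.0, range: [13785.0, 22976.0], dist: gamma}
cost_iv_infusion: {value: 15.6, range: [5.0, 30.0], dist: gamma}

# --- Run configuration ---
discount_rate: {value: 0.05, range: [0.0, 0.08]}
start_age: {value: 67}
horizon_years: {value: 30}
cycle_length: {value: 0.25}
n_markov_cycles: {value: 119}
body_weight: {value: 75.0, range: [40.0, 100.0]}
dose_per_kg: {value: 0.25}
dose_cap_mg: {value: 25.0}
wtp_threshold: {value: 89358.0}
half_cycle_correction: {value: true}
# sICH utility decrement convention: false = rate for the 3-month tree period
# (QALY loss 0.38 * 0.25 per case); true = one-off absolute loss of 0.38 QALY.
sich_disutility_absolute: {value: false}
# Whether reported life-years are discounted like QALYs (undiscounted LY are
# always emitted alongside).
discount_life_years: {value: true}
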