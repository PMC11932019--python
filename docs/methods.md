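# Methods

This note documents the model implemented in `strokecea`: its structure and
assumptions, the conventions chosen where the original analysis left them
open, the uncertainty machinery, what the synthetic-trial generator does and
does not emulate, and known limitations.

## Model structure

The question is the cost-utility, from the Chinese healthcare-system
perspective (direct medical costs only, 2023 CNY), of adding intravenous
tenecteplase (0.25 mg/kg, max 25 mg, single bolus) to standard medical care
for acute ischemic stroke due to large-vessel occlusion treated 4.5–24 h
after onset when thrombectomy is not available. The cohort enters at age 67
(base case) and is followed for 30 years.

**Decision tree, months 0–3.** The 90-day outcome is a multinomial over mRS
0–6 (6 = death). The standard-care distribution is an input; the
tenecteplase distribution is `base × RR` renormalized to sum to one
(raw deficit ≈ 0.4% at the point estimates). Renormalization, rather than
reading the treated arm's distribution directly, keeps any draw of the RR
vector internally coherent in the sensitivity analyses. Acute costs are
class-based (mRS 0–1 / 2–5 / death), plus the expected extra cost of
symptomatic intracranial hemorrhage (sICH) and, in the treated arm, the
weight-based drug cost and infusion fee. QALYs credit each 90-day state its
utility for the quarter. No within-window dynamics beyond sICH are modelled
(none are specified by the source data).

**Markov cohort, cycles 1–119 (quarterly).** Alive states mRS 0–5; death is
absorbing. Each cycle resolves at most one clinical event per patient:

1. recurrent stroke, with per-cycle probability p = 1 − (1 − 0.112)^¼
   (constant-hazard annual→quarter conversion). A recurrence is fatal with
   event-conditional probability 0.21 (applied as given, not re-converted,
   since it conditions on the event rather than on time); survivors are
   redistributed uniformly over their current-or-worse mRS levels and carry
   the recurrence utility (0.42) for that cycle;
2. otherwise background death, from the age-band life table converted on
   the rate scale and multiplied by the state's mortality hazard ratio
   (−ln(1 − q)·HR/4, back-converted);
3. otherwise no event: the patient stays in state. There is no spontaneous
   improvement or deterioration between recurrences, so the
   "no transition to a lower disability level after recurrence" assumption
   holds without tunnel states.

Event ordering — recurrence first, background mortality only on the
no-recurrence branch — enforces the one-event-per-cycle assumption and makes
the branch probabilities sum to one exactly.

## Accumulation and discounting conventions

Where the source description is silent, the following conventions are used
(each was chosen once as the standard variant; together they reproduce the
reference base case to ~1% on the increments and ~5% on arm totals):

- **Half-cycle correction**: trapezoidal — state-occupancy cost, QALY and
  life-year streams are valued on the average of start- and end-of-cycle
  occupancy. Recurrent-stroke events are priced per event (18,380 CNY,
  fatal or not; no separate acute-death cost inside the Markov phase), and
  the recurrence-utility substitution for surviving recurrences replaces the
  occupancy-implied valuation for the event cycle.
- **Discounting**: 5%/yr (range 0–8%) as (1+r)^(−t), clock starting at model
  entry; the first Markov cycle is discounted at t = 0.25 yr. The decision
  tree (first quarter) is undiscounted.
- **Life-years** are reported discounted, matching QALYs; undiscounted
  totals are always emitted alongside (`total_ly_undisc`). The discounted
  convention reproduces the reference life-expectancy figures (7.25 vs 7.30
  reported for standard care); the undiscounted ones (~10.5) clearly do not.
- **sICH disutility**: 0.38 interpreted as a utility-rate decrement applied
  for the 3-month tree window (QALY loss 0.38 × 0.25 per case); a config
  switch (`sich_disutility_absolute`) charges the full 0.38 QALY one-off
  instead. The rate convention is the default and matches the reference
  increments slightly better; the difference is ~0.001 QALY per arm.
- **Ages beyond the life table**: the last band (85+) applies for the rest
  of the horizon. Ages *below* the first band (relevant when the start age
  is set under 67, e.g. the age-60 scenario) reuse the first band's value —
  a slight overstatement of mortality for ages 60–66, as the bundled table
  starts at 67.
- The published month-3 mRS point values sum to 0.999 (rounding); the
  loaded base distribution is renormalized once (÷0.999).

## Parameters

All inputs live in `strokecea/data/table1_defaults.yaml` with value, range
and PSA family; every scalar is addressable by its flat name in overrides,
tornado and threshold search. The consequential ones:

| parameter | default | units | role |
|---|---|---|---|
| `mrs3mo_std_0..6` | 0.067…0.131 | prob. | 90-day mRS distribution, standard care |
| `rr_mrs0..6` | 1.46…1.01 | ratio | treatment effect per mRS category |
| `p_sich_tnk` / `p_sich_std` | 0.019 / 0.008 | prob. | acute sICH risk |
| `annual_recurrence` | 0.112 | /yr | recurrent-stroke risk (constant over the horizon) |
| `p_death_after_recurrence` | 0.21 | per event | recurrence case fatality |
| `hr_mrs0..5` | 1…2.37 | ratio | mortality hazard ratio by state |
| `u_mrs0..5`, `u_recurrence`, `d_sich` | 0.95…0.1, 0.42, 0.38 | utility/yr | health-state values |
| `cost_*` | see file | 2023 CNY | acute, post-hospitalization, event and drug costs |
| `discount_rate` | 0.05 | /yr | costs, QALYs and (by default) LYs |
| `start_age` / `horizon_years` / `n_markov_cycles` | 67 / 30 / 119 | — | cohort and horizon |
| `body_weight` | 75 (40–100) | kg | drug dose = min(0.25·kg, 25) mg |
| `wtp_threshold` | 89,358 | CNY/QALY | 1× 2023 per-capita GDP |

Costs are already in 2023 CNY; `cpi_adjust` exposes the healthcare CPI
chain (2015–2023 factors, cumulative product ≈ 1.2546 from 2014) for
re-basing older cost data.

## Sensitivity analyses

**One-way (tornado).** Every input with a published range (43 rows,
including the discount rate and body weight) is pushed to each bound with
all else at base case. Perturbing one mRS category rescales the other six
proportionally so the vector stays a distribution. Ends where one strategy
dominates are flagged as a category rather than shown as a negative ICER.

**Probabilistic.** Method-of-moments fits treating each range as a 95%
interval (sd = width/3.92): gamma for costs (shape = m²/σ², scale = σ²/m),
beta for probabilities and utilities (via the mean/variance
reparameterization; infeasible variances are clipped with a logged
warning), lognormal for risk and hazard ratios with the point value as the
median (μ = ln point, σ = Δln/3.92 — means of ratio parameters therefore sit
up to ~5% above the point value, which is inherent to treating the point as
a median), and one Dirichlet for the month-3 block with effective sample
size calibrated so the mRS-0 marginal reproduces its published interval
(N ≈ 249, consistent with the originating trial's arm size). Draws are
independent across rows except the Dirichlet block; the treated arm's
distribution is re-derived per draw. Sampling uses one master seed with
per-draw substreams, so extending the number of draws never changes earlier
draws. The CEAC reports, per willingness-to-pay value, the fraction of
draws with positive incremental net monetary benefit; the crossover is the
50% point by grid bracketing and linear interpolation.

The Markov arithmetic is implemented once, vectorized over a draw batch, so
the deterministic pipeline and the Monte-Carlo loop cannot drift apart; a
test pins point-mass draws to the base case at 1e-8.

## Synthetic-trial generator

`strokecea.trial` emulates the statistical structure of the trial-derived
inputs only: two arms of n patients (default 250, matching the scale
implied by the published interval widths), multinomial 90-day mRS counts,
binomial sICH counts, risk ratios estimated as proportion ratios with the
standard log-scale two-proportion standard error and a 0.5 continuity
correction for zero cells. It does **not** simulate patient-level
covariates, time-to-event follow-up, dropout, or site effects — so
passing parameter-recovery tests show that the pipeline consumes
trial-shaped uncertainty correctly, not that it would be robust to
real-world trial pathologies. `trial_to_parameters` splices the estimates
(values and intervals) into a template parameter set, leaving all
non-trial rows untouched, and rejects trials with a category empty in both
arms.

## Numerical choices

- Probability conservation is enforced per cycle at 1e-9; seeds must sum
  to 1 at 1e-9.
- Rate↔probability conversions use `log1p`/`expm1` for small-probability
  accuracy and satisfy the round-trip identity to 1e-12.
- Threshold search uses Brent bisection at 1e-6 relative tolerance and
  reports "no threshold" when the objective has equal signs at the ends.
- ICER is undefined at ΔE = 0; classification falls back to the sign of ΔC.
  Dominance labels: dominant (ΔC<0, ΔE>0), dominated (ΔC>0, ΔE<0),
  southwest trade-off (both negative), GDP-multiple bands otherwise.
- Validation is strict on user-supplied sets (probabilities in [0,1],
  utilities in [0,1] with u(death)=0, HR ≥ 1, costs ≥ 0, contiguous
  open-ended life table). Monotonicity of utilities/HRs across mRS holds at
  the base case but is deliberately not enforced, so one-way bounds and PSA
  draws that cross a neighbour remain evaluable.

## Known limitations and deviations

- **Scenario "start age 75"** yields ICER ≈ 9,510 CNY/QALY here versus a
  reported 7,515. The reported 6.63 discounted life-years for a
  standard-care cohort starting at 75 is reproducible from the 75+ life
  table only if the mRS mortality hazard ratios are dropped — which would
  in turn break the base case (≈8.1 instead of 7.30 LY). The hazard ratios
  are kept in all scenarios; the published ICER ordering across scenarios
  (age 60 < base < age 75 < max dose < pre-procurement price) holds
  exactly.
- **Tornado at rr_mrs6 = 1.58**: reported as making tenecteplase dominated
  (worse and costlier). Under the base×RR renormalization, raising the
  mortality risk ratio scales every alive seed category down by the same
  factor (0.93 at 1.58), so lifetime QALYs of the treated arm remain above
  standard care (ΔE would turn negative only near rr6 ≈ 2), and the extra
  early deaths *reduce* lifetime cost — the model classifies this bound as
  dominant, the opposite corner. Likewise the low bound of
  `cost_posthosp_mrs01` makes tenecteplase marginally cost-saving
  (ICER ≈ −1,520), just outside the reported 0–25,000 window; all other 41
  bounds stay inside it.
- **PSA spread**: under independent sampling at 95%-interval widths the
  incremental-cost cloud has sd ≈ 4.6k CNY, giving ≈24% dominant and ≈73%
  highly cost-effective draws (the reported split is 2.3%/97.7%). The
  drug-price gamma alone (sd ≈ 1.65k on the per-treatment cost) accounts
  for roughly the whole reported dominant fraction, so a materially tighter
  cloud would require correlating or shrinking the published ranges. The
  CEAC crossover (~7.1k CNY/QALY at 10,000 draws) and the qualitative
  conclusion — tenecteplase preferred at any plausible willingness to
  pay — are unaffected.
- Constant recurrence risk over 30 years; no asymptomatic hemorrhage or
  other adverse events; no microsimulation (cohort-level only); no
  currency conversion; background mortality below age 67 approximated by
  the first life-table band.
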