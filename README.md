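# strokecea

Cost-utility analysis of intravenous tenecteplase for acute ischemic stroke
treated **4.5–24 h after onset without thrombectomy**, from the Chinese
healthcare-system perspective.

Most stroke patients arrive too late for standard-window thrombolysis, and in
many regions mechanical thrombectomy is unavailable. Late-window tenecteplase
improves 90-day functional outcome (modified Rankin Scale, mRS) in this
population; `strokecea` asks what that benefit costs. It is a library for
health economists and methodologists: a fully parameterized decision-analytic
model with deterministic and probabilistic sensitivity analysis, scenario
analysis, and a synthetic-trial generator for the trial-derived inputs.

## Model

A hybrid **decision tree + Markov cohort model**:

- **Decision tree (first 3 months).** Each arm's 90-day mRS distribution is
  the terminal-node layer. The tenecteplase arm's distribution is the
  standard-care distribution reweighted by per-category risk ratios
  RR₀…RR₆ and renormalized. Acute costs (admission by mRS class, extra cost
  and disutility of symptomatic intracranial hemorrhage, weight-based drug
  cost: 0.25 mg/kg capped at 25 mg) and 3-month QALYs accrue here,
  undiscounted.
- **Markov model (quarterly cycles 1–119, 30-year horizon).** Seven states:
  mRS 0–5 and death. Per cycle an alive patient experiences exactly one of
  *no event*, *recurrent stroke* (annual risk R = 0.112 converted via
  p = 1 − (1 − R)^¼; fatal with probability 0.21, survivors redistributed
  uniformly over same-or-worse mRS), or *background death* (age-band life
  table scaled on the rate scale by mRS-specific hazard ratios).
  State-occupancy costs (annual post-hospitalization care by mRS class),
  QALYs (state utilities; recurrence cycles at the recurrence utility) and
  life-years accumulate with a trapezoidal half-cycle correction and are
  discounted at 5%/yr.
- **Outputs.** Per-arm lifetime cost C, QALYs E and life-years; increments
  ΔC, ΔE; **ICER = ΔC/ΔE**, judged against λ = 89,358 CNY/QALY (2023
  per-capita GDP; "highly cost-effective" below 1×, "cost-effective" below
  3×).
- **Uncertainty.** One-way tornado over every input's published range;
  probabilistic sensitivity analysis with method-of-moments marginals
  (gamma costs, beta probabilities/utilities, Dirichlet month-3 mRS block,
  lognormal risk/hazard ratios), incremental cost-effectiveness cloud and
  cost-effectiveness acceptability curve.

All inputs ship with the package (`strokecea/data/table1_defaults.yaml`,
2023 CNY) and every scalar can be overridden by flat name.

## Worked example

```bash
python examples/run_base_case.py
```

prints

```
Standard treatment   cost    118,859 CNY   QALY  2.98   LY  7.25
Tenecteplase         cost    121,427 CNY   QALY  3.38   LY  7.31
Increment            cost      2,567 CNY   QALY  0.40   LY  0.06
ICER: 6,391 CNY/QALY   [highly cost-effective]
```

Adding tenecteplase costs 2,567 CNY extra per patient over a lifetime and
gains 0.40 QALYs, so a QALY costs 6,391 CNY — about 7% of the
willingness-to-pay threshold. The other examples
(`run_scenarios.py`, `run_tornado.py`, `run_psa.py`,
`run_synthetic_trial.py`) walk through the scenario, one-way and
probabilistic analyses and the synthetic-trial workflow the same way.

The same stages are available from the shell:

```bash
stroke-cea base-case --out-dir results/
stroke-cea psa --n-draws 10000 --seed 2023 --out-dir results/
stroke-cea scenario --scenario-id 1 --out-dir results/
```

Each command writes CSV/JSON tables plus a run manifest (config hash, seed,
version, file list) for bit-exact reproduction.

## Library sketch

```python
from strokecea import load_parameters, evaluate, run_psa

params = load_parameters(overrides={"discount_rate": 0.0})
result = evaluate(params)          # CEResult: arm totals, ΔC, ΔE, ICER
psa    = run_psa(params, 10_000, seed=2023)
```

`params.with_overrides({...})` returns a new validated set; the sensitivity
modules (`strokecea.dsa`, `strokecea.psa`) and the synthetic-trial tools
(`strokecea.trial`) all operate on the same `ParameterSet`.

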