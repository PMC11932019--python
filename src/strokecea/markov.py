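"""Long-term Markov cohort engine and arm comparison.

Beyond month 3 the cohort is simulated over 119 quarterly cycles across seven
states (mRS 0-5 and death). Each cycle an alive patient experiences exactly
one of: recurrent stroke (annual risk converted to a cycle probability;
fatal with the event-conditional case fatality, otherwise redistributed
uniformly over the same-or-worse mRS levels), background death (age-band
mortality scaled on the rate scale by the mRS-specific hazard ratio), or no
event (remain in state). There is no spontaneous migration between mRS levels
absent a recurrence.

Accumulation uses a trapezoidal half-cycle correction (average of start- and
end-of-cycle occupancies) for the state-occupancy cost, QALY and life-year
streams; recurrent-stroke events are priced per event, and recurrence
survivors are valued at the recurrence utility for the cycle of the event.
All streams are discounted at ``(1 + r)^(-t)`` with the first Markov cycle at
t = 0.25 years after model entry.

The cycle arithmetic is implemented once, vectorized over a leading batch
axis, so the deterministic base case, the sensitivity analyses and the
Monte-Carlo loop share a single code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision_tree import ArmOutcome3mo, three_month_outcomes
from .params import (
    EpidemiologyParams,
    MRSDistribution,
    ModelConfig,
    N_MRS,
    ParameterSet,
    ParameterValidationError,
    annual_rate_to_cycle_prob,
)

QUARTER = 0.25

__all__ = [
    "CycleTrace",
    "ArmResult",
    "CEResult",
    "redistribute_after_recurrence",
    "background_mortality_prob",
    "cycle_transition",
    "run_cohort",
    "compare_arms",
    "evaluate",
]

# Redistribution after a survived recurrence: uniform over the same-or-worse
# alive mRS levels. _REDIST[i, j] = 1/(6 - i) for j >= i.
_REDIST = np.zeros((6, 6))
for _i in range(6):
    _REDIST[_i, _i:] = 1.0 / (6 - _i)
_REDIST.setflags(write=False)


def redistribute_after_recurrence(state: int) -> np.ndarray:
    """Post-recurrence destination distribution over mRS 0-5.

    Survivors of a recurrent stroke are spread uniformly over their current
    and all more severe disability levels; death (mRS 6) cannot recur.
    """
    if not 0 <= state <= 5:
        raise ParameterValidationError(
            f"recurrence redistribution defined for mRS 0-5, got {state}"
        )
    return np.array(_REDIST[state])


def background_mortality_prob(age: float, state: int,
                              epi: EpidemiologyParams) -> float:
    """Per-cycle non-stroke mortality for an age and mRS state.

    The annual age-band probability is moved to the rate scale
    (``-ln(1 - q)``), scaled by the state's hazard ratio, divided by four,
    and converted back to a probability.
    """
    if not 0 <= state <= 5:
        raise ParameterValidationError(f"state must be mRS 0-5, got {state}")
    q_annual = epi.annual_mortality(age)
    rate = -np.log1p(-q_annual) * epi.hr_mrs[state] / 4.0
    return float(-np.expm1(-rate))


@dataclass(frozen=True)
class CycleStep:
    """One-cycle transition for a single origin state (diagnostic view)."""

    probs: np.ndarray          # length 7 distribution over next-cycle states
    p_recurrence: float        # probability of a recurrent-stroke event
    p_recurrence_death: float  # fatal-recurrence probability
    p_background_death: float  # non-stroke death probability


def cycle_transition(state: int, age: float, params: ParameterSet) -> CycleStep:
    """Event-resolved one-cycle transition distribution for one origin state.

    Recurrence is resolved first; background mortality applies only on the
    no-recurrence branch, so each patient experiences at most one clinical
    event per cycle and the branch probabilities sum to one.
    """
    if not 0 <= state <= 5:
        raise ParameterValidationError(
            f"transitions defined for alive states mRS 0-5, got {state}"
        )
    epi = params.epidemiology
    p_rec = annual_rate_to_cycle_prob(epi.annual_recurrence)
    p_dr = epi.p_death_after_recurrence
    p_bg = background_mortality_prob(age, state, epi)

    probs = np.zeros(N_MRS)
    probs[:6] += p_rec * (1.0 - p_dr) * redistribute_after_recurrence(state)
    probs[state] += (1.0 - p_rec) * (1.0 - p_bg)
    probs[6] = p_rec * p_dr + (1.0 - p_rec) * p_bg
    return CycleStep(
        probs=probs,
        p_recurrence=p_rec,
        p_recurrence_death=p_rec * p_dr,
        p_background_death=(1.0 - p_rec) * p_bg,
    )


# ---------------------------------------------------------------------------
# Batched engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _BatchInputs:
    """Per-draw model inputs as arrays with a leading batch axis of size B."""

    u_alive: np.ndarray        # (B, 6) state utilities, mRS 0-5
    u_recurrence: np.ndarray   # (B,)
    posthosp_alive: np.ndarray  # (B, 6) annual care cost by alive state
    cost_recurrent: np.ndarray  # (B,)
    p_rec: np.ndarray          # (B,) per-cycle recurrence probability
    p_death_rec: np.ndarray    # (B,)
    hr: np.ndarray             # (B, 6)
    discount_rate: np.ndarray  # (B,)
    epi: EpidemiologyParams    # age-band lookup (shared across the batch)
    start_age: float
    n_cycles: int
    half_cycle_correction: bool


def _batch_inputs(params: ParameterSet) -> _BatchInputs:
    epi = params.epidemiology
    return _BatchInputs(
        u_alive=params.utilities.u_mrs[None, :6],
        u_recurrence=np.array([params.utilities.u_recurrence]),
        posthosp_alive=params.costs.posthosp_annual_by_state()[None, :6],
        cost_recurrent=np.array([params.costs.recurrent_stroke]),
        p_rec=np.array([annual_rate_to_cycle_prob(epi.annual_recurrence)]),
        p_death_rec=np.array([epi.p_death_after_recurrence]),
        hr=epi.hr_mrs[None, :],
        discount_rate=np.array([params.config.discount_rate]),
        epi=epi,
        start_age=params.config.start_age,
        n_cycles=params.config.n_markov_cycles,
        half_cycle_correction=params.config.half_cycle_correction,
    )


def _run_markov_batch(seeds: np.ndarray, inp: _BatchInputs,
                      collect_trace: bool = False) -> dict:
    """Iterate the cohort over all cycles for a batch of parameter draws.

    ``seeds`` is (B, 7); returns discounted and undiscounted cost/QALY/LY
    totals of shape (B,), plus per-cycle trace arrays when requested.
    """
    x = np.array(seeds, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_MRS:
        raise ParameterValidationError(f"seeds must be (B, {N_MRS})")
    if np.any(np.abs(x.sum(axis=1) - 1.0) > 1e-9):
        raise ParameterValidationError("each seed distribution must sum to 1")
    B = x.shape[0]
    hcc = inp.half_cycle_correction

    totals = {k: np.zeros(B) for k in
              ("cost", "qaly", "ly", "cost_undisc", "qaly_undisc", "ly_undisc")}
    trace: list[dict] = []

    for k in range(1, inp.n_cycles + 1):
        age = inp.start_age + QUARTER * k
        q_annual = inp.epi.annual_mortality(age)
        # rate-scale HR adjustment, quarterly
        p_bg = -np.expm1(np.log1p(-q_annual) * inp.hr / 4.0)  # (B, 6)

        alive = x[:, :6]
        rec = alive * inp.p_rec[:, None]
        rec_death = rec * inp.p_death_rec[:, None]
        rec_surv = rec - rec_death
        nonrec = alive - rec
        bg_death = nonrec * p_bg
        stay = nonrec - bg_death

        alive_new = stay + rec_surv @ _REDIST
        x_new = np.empty_like(x)
        x_new[:, :6] = alive_new
        x_new[:, 6] = x[:, 6] + rec_death.sum(axis=1) + bg_death.sum(axis=1)

        if hcc:
            occ = 0.5 * (alive + alive_new)
        else:
            occ = alive_new
        events = rec.sum(axis=1)
        cost_k = QUARTER * (occ * inp.posthosp_alive).sum(axis=1) \
            + events * inp.cost_recurrent
        ly_k = QUARTER * occ.sum(axis=1)
        # Recurrence survivors spend the event cycle at the recurrence
        # utility rather than the occupancy-implied state utilities.
        dest_u = rec_surv @ _REDIST * inp.u_alive  # mass-weighted dest utility
        if hcc:
            occ_u = 0.5 * ((alive * inp.u_alive).sum(axis=1)
                           + (alive_new * inp.u_alive).sum(axis=1))
            implied = 0.5 * ((rec_surv * inp.u_alive).sum(axis=1)
                             + dest_u.sum(axis=1))
        else:
            occ_u = (alive_new * inp.u_alive).sum(axis=1)
            implied = dest_u.sum(axis=1)
        corr = rec_surv.sum(axis=1) * inp.u_recurrence - implied
        qaly_k = QUARTER * (occ_u + corr)

        t = QUARTER * k
        df = (1.0 + inp.discount_rate) ** (-t)
        totals["cost"] += cost_k * df
        totals["qaly"] += qaly_k * df
        totals["ly"] += ly_k * df
        totals["cost_undisc"] += cost_k
        totals["qaly_undisc"] += qaly_k
        totals["ly_undisc"] += ly_k

        if collect_trace:
            trace.append({
                "cycle": k, "age": age,
                "occupancy": x_new[0].copy(),
                "cost": float(cost_k[0]), "cost_disc": float((cost_k * df)[0]),
                "qaly": float(qaly_k[0]), "qaly_disc": float((qaly_k * df)[0]),
                "ly": float(ly_k[0]), "ly_disc": float((ly_k * df)[0]),
            })
        x = x_new

    totals["final_occupancy"] = x
    if collect_trace:
        totals["trace"] = trace
    return totals


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleTrace:
    """Per-cycle state occupancy and (un)discounted accumulators."""

    cycle: np.ndarray       # (n,)
    age: np.ndarray         # (n,)
    occupancy: np.ndarray   # (n, 7), end-of-cycle
    cost: np.ndarray
    cost_disc: np.ndarray
    qaly: np.ndarray
    qaly_disc: np.ndarray
    ly: np.ndarray
    ly_disc: np.ndarray

    @classmethod
    def from_records(cls, records: list[dict]) -> "CycleTrace":
        return cls(
            cycle=np.array([r["cycle"] for r in records]),
            age=np.array([r["age"] for r in records]),
            occupancy=np.array([r["occupancy"] for r in records]),
            cost=np.array([r["cost"] for r in records]),
            cost_disc=np.array([r["cost_disc"] for r in records]),
            qaly=np.array([r["qaly"] for r in records]),
            qaly_disc=np.array([r["qaly_disc"] for r in records]),
            ly=np.array([r["ly"] for r in records]),
            ly_disc=np.array([r["ly_disc"] for r in records]),
        )


@dataclass(frozen=True)
class ArmResult:
    """Lifetime totals for one arm (decision tree + Markov phases)."""

    arm: str
    total_cost: float
    total_qaly: float
    total_ly: float            # discounted or not per config.discount_life_years
    total_ly_undisc: float
    markov_cost: float
    markov_qaly: float
    three_month: ArmOutcome3mo | None = None
    trace: CycleTrace | None = None


@dataclass(frozen=True)
class CEResult:
    """Head-to-head comparison of the two strategies."""

    standard: ArmResult
    tenecteplase: ArmResult
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None
    classification: str
    wtp_threshold: float

    def summary(self) -> dict:
        return {
            "standard": {"cost": self.standard.total_cost,
                         "qaly": self.standard.total_qaly,
                         "ly": self.standard.total_ly},
            "tenecteplase": {"cost": self.tenecteplase.total_cost,
                             "qaly": self.tenecteplase.total_qaly,
                             "ly": self.tenecteplase.total_ly},
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "icer": self.icer,
            "classification": self.classification,
            "wtp_threshold": self.wtp_threshold,
        }


def run_cohort(seed_dist: MRSDistribution, params: ParameterSet,
               three_month: ArmOutcome3mo | None = None,
               collect_trace: bool = True) -> ArmResult:
    """Simulate the Markov phase from a month-3 seed distribution.

    When the arm's decision-tree outcome is supplied its (undiscounted)
    acute-phase cost, QALYs and life-years are folded into the totals, giving
    full lifetime figures.
    """
    inp = _batch_inputs(params)
    out = _run_markov_batch(seed_dist.as_array()[None, :], inp,
                            collect_trace=collect_trace)
    tree_cost = three_month.cost if three_month else 0.0
    tree_qaly = three_month.qaly if three_month else 0.0
    tree_ly = three_month.ly if three_month else 0.0
    ly_key = "ly" if params.config.discount_life_years else "ly_undisc"
    return ArmResult(
        arm=three_month.arm if three_month else "cohort",
        total_cost=tree_cost + float(out["cost"][0]),
        total_qaly=tree_qaly + float(out["qaly"][0]),
        total_ly=tree_ly + float(out[ly_key][0]),
        total_ly_undisc=tree_ly + float(out["ly_undisc"][0]),
        markov_cost=float(out["cost"][0]),
        markov_qaly=float(out["qaly"][0]),
        three_month=three_month,
        trace=CycleTrace.from_records(out["trace"]) if collect_trace else None,
    )


def classify(delta_cost: float, delta_qaly: float, icer: float | None,
             wtp: float) -> str:
    """Decision label from the increments and the GDP-multiple rule.

    ``highly cost-effective`` below 1x per-capita GDP per QALY,
    ``cost-effective`` between 1x and 3x, ``not cost-effective`` above 3x;
    strict dominance when one strategy is both cheaper and more effective.
    """
    if delta_qaly > 0 and delta_cost < 0:
        return "dominant"
    if delta_qaly < 0 and delta_cost > 0:
        return "dominated"
    if delta_qaly == 0:
        if delta_cost == 0:
            return "equivalent"
        return "cost-saving" if delta_cost < 0 else "costlier, equal effect"
    if delta_qaly < 0:  # delta_cost <= 0: cheaper but less effective
        return "southwest trade-off"
    assert icer is not None
    if icer < wtp:
        return "highly cost-effective"
    if icer < 3 * wtp:
        return "cost-effective"
    return "not cost-effective"


def compare_arms(std: ArmResult, tnk: ArmResult, cfg: ModelConfig) -> CEResult:
    """Increments, ICER and dominance classification for tenecteplase vs standard."""
    d_cost = tnk.total_cost - std.total_cost
    d_qaly = tnk.total_qaly - std.total_qaly
    d_ly = tnk.total_ly - std.total_ly
    icer = d_cost / d_qaly if d_qaly != 0 else None
    return CEResult(
        standard=std, tenecteplase=tnk,
        delta_cost=d_cost, delta_qaly=d_qaly, delta_ly=d_ly,
        icer=icer,
        classification=classify(d_cost, d_qaly, icer, cfg.wtp_threshold),
        wtp_threshold=cfg.wtp_threshold,
    )


def evaluate(params: ParameterSet, collect_trace: bool = False) -> CEResult:
    """Run the full pipeline (both arms, tree + Markov) for one parameter set."""
    results = {}
    for arm in ("standard", "tenecteplase"):
        tree = three_month_outcomes(arm, params)
        results[arm] = run_cohort(tree.mrs_dist, params, three_month=tree,
                                  collect_trace=collect_trace)
    return compare_arms(results["standard"], results["tenecteplase"],
                        params.config)
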