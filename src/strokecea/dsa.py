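"""Deterministic sensitivity analysis: tornado, scenarios, threshold search.

One-way analysis re-evaluates the full pipeline with a single input pushed to
each end of its published range, everything else at base case. For the
month-3 mRS block, perturbing one category rescales the other six
proportionally so the vector remains a distribution. Scenario analysis
re-runs the pipeline under named override bundles (pre-procurement drug
price, maximum dose, alternative cohort start ages).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from scipy.optimize import brentq

from .markov import CEResult, evaluate
from .params import ParameterSet

__all__ = [
    "TornadoRow",
    "ScenarioSpec",
    "SCENARIOS",
    "one_way",
    "tornado",
    "run_scenario",
    "threshold_search",
]


@dataclass(frozen=True)
class TornadoRow:
    """ICER at both ends of one parameter's range."""

    parameter: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None
    classification_low: str
    classification_high: str
    span: float  # |icer_high - icer_low| when both defined, else nan

    @property
    def dominance_flagged(self) -> bool:
        return self.icer_low is None or self.icer_high is None or \
            "domina" in self.classification_low or "domina" in self.classification_high


def one_way(param_name: str, low: float, high: float,
            params: ParameterSet) -> TornadoRow:
    """Evaluate the model with ``param_name`` at each bound of [low, high]."""
    base = params.get(param_name)
    if not (low - 1e-12 <= base <= high + 1e-12):
        raise ValueError(
            f"{param_name}: base value {base} outside [{low}, {high}]"
        )
    res_low = evaluate(params.with_overrides({param_name: low}))
    res_high = evaluate(params.with_overrides({param_name: high}))
    span = (abs(res_high.icer - res_low.icer)
            if res_low.icer is not None and res_high.icer is not None
            else float("nan"))
    return TornadoRow(
        parameter=param_name, low=low, high=high,
        icer_low=res_low.icer, icer_high=res_high.icer,
        classification_low=res_low.classification,
        classification_high=res_high.classification,
        span=span,
    )


def tornado(params: ParameterSet,
            parameters: Sequence[str] | None = None) -> list[TornadoRow]:
    """One-way rows for every ranged input, sorted by descending ICER span.

    Rows whose span is undefined because an endpoint is dominant/dominated
    sort first (they are the most consequential) and carry a dominance flag.
    """
    names = list(parameters) if parameters is not None else params.ranged_parameters()
    rows = [one_way(name, *params.ranges[name], params) for name in names]

    def _key(row: TornadoRow):
        flagged = row.icer_low is None or row.icer_high is None or row.dominance_flagged
        return (0 if flagged else 1, -(row.span if row.span == row.span else 0.0))

    return sorted(rows, key=_key)


@dataclass(frozen=True)
class ScenarioSpec:
    """Named bundle of parameter overrides defining a scenario."""

    scenario_id: str
    description: str
    overrides: Mapping[str, object] = field(default_factory=dict)


#: The four published scenarios plus the base case.
SCENARIOS: dict[str, ScenarioSpec] = {
    "base": ScenarioSpec("base", "Base case (no overrides)", {}),
    "1": ScenarioSpec(
        "1",
        "Tenecteplase at its pre-procurement market price (459.4 CNY/mg)",
        {"cost_tnk_per_mg": 459.4},
    ),
    "2": ScenarioSpec(
        "2",
        "Maximum dose for every patient (100 kg weight -> 25 mg cap)",
        {"body_weight": 100.0},
    ),
    "3": ScenarioSpec("3", "Cohort starting age 60 years", {"start_age": 60.0}),
    "4": ScenarioSpec("4", "Cohort starting age 75 years", {"start_age": 75.0}),
}


def run_scenario(spec: ScenarioSpec, params: ParameterSet) -> CEResult:
    """Full pipeline under a scenario's overrides."""
    for name in spec.overrides:
        params.get(name)  # raises KeyError with guidance for unknown names
    return evaluate(params.with_overrides(spec.overrides))


def threshold_search(param_name: str,
                     objective: Callable[[CEResult], float],
                     params: ParameterSet,
                     low: float | None = None,
                     high: float | None = None,
                     rtol: float = 1e-6) -> float | None:
    """Parameter value at which an objective of the comparison crosses zero.

    ``objective`` maps a :class:`~strokecea.markov.CEResult` to a scalar
    (e.g. ``lambda r: r.icer - wtp`` or ``lambda r: r.delta_qaly``). The
    search interval defaults to the parameter's published range. Returns the
    crossing value found by bisection (Brent), or ``None`` when the objective
    has the same sign at both ends ("no threshold in range").
    """
    if low is None or high is None:
        if param_name not in params.ranges:
            raise ValueError(
                f"{param_name} has no published range; pass low/high explicitly"
            )
        rlo, rhi = params.ranges[param_name]
        low = rlo if low is None else low
        high = rhi if high is None else high

    def f(value: float) -> float:
        return objective(evaluate(params.with_overrides({param_name: value})))

    f_lo, f_hi = f(low), f(high)
    if f_lo == 0:
        return low
    if f_hi == 0:
        return high
    if f_lo * f_hi > 0:
        return None
    return float(brentq(f, low, high, rtol=rtol))
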