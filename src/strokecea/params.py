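"""Model inputs for the tenecteplase cost-utility model.

Every quantity the model consumes lives here as a typed, validated parameter:
the 90-day modified Rankin Scale (mRS) outcome distribution under standard
care, the per-category risk ratios for the tenecteplase arm, symptomatic
intracranial hemorrhage (sICH) probabilities, long-term epidemiology
(recurrence, case fatality, mortality hazard ratios, background life tables),
health-state utilities, unit costs in 2023 CNY, and the run configuration
(cohort start age, horizon, cycle length, discount rate, dosing, willingness
to pay).

The module also owns the arithmetic shared by everything downstream:
annual-rate to cycle-probability conversion, healthcare CPI inflation to 2023
CNY, and weight-based drug-cost computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

N_MRS = 7  # mRS 0..5 plus death (mRS 6)

__all__ = [
    "N_MRS",
    "ParameterValidationError",
    "MRSDistribution",
    "RiskRatioVector",
    "UtilitySet",
    "CostSet",
    "EpidemiologyParams",
    "ModelConfig",
    "ParameterSet",
    "annual_rate_to_cycle_prob",
    "cycle_prob_to_annual_rate",
    "cpi_adjust",
    "tenecteplase_dose",
    "tnk_drug_cost",
    "load_parameters",
    "HEALTHCARE_CPI",
]


class ParameterValidationError(ValueError):
    """Raised when a parameter value violates its domain; names the field."""


# ---------------------------------------------------------------------------
# Rate / probability conversions
# ---------------------------------------------------------------------------

CYCLES_PER_YEAR = 4


def annual_rate_to_cycle_prob(annual_prob: float) -> float:
    """Convert an annual event probability to a 3-month transition probability.

    Assumes a constant hazard within the year: the annual probability ``R`` is
    first converted to a 3-month rate ``r = -ln(1 - R) / 4`` and then back to a
    probability ``p = 1 - exp(-r)``, which collapses to
    ``p = 1 - (1 - R)**(1/4)``.

    Parameters
    ----------
    annual_prob:
        Annual probability of the event, in ``[0, 1)``.

    Returns
    -------
    float
        Per-cycle (3-month) transition probability; always ``<= annual_prob``.
    """
    R = float(annual_prob)
    if not 0.0 <= R < 1.0:
        raise ParameterValidationError(
            f"annual probability must be in [0, 1), got {R!r}"
        )
    return 1.0 - (1.0 - R) ** (1.0 / CYCLES_PER_YEAR)


def cycle_prob_to_annual_rate(cycle_prob: float) -> float:
    """Inverse of :func:`annual_rate_to_cycle_prob` (constant-hazard model)."""
    p = float(cycle_prob)
    if not 0.0 <= p < 1.0:
        raise ParameterValidationError(
            f"cycle probability must be in [0, 1), got {p!r}"
        )
    return 1.0 - (1.0 - p) ** CYCLES_PER_YEAR


# ---------------------------------------------------------------------------
# CPI adjustment
# ---------------------------------------------------------------------------

#: Year-over-year healthcare CPI factors for China; the factor keyed by year y
#: inflates a cost from year y-1 terms into year y terms.
HEALTHCARE_CPI: dict[int, float] = {
    2015: 1.027,
    2016: 1.038,
    2017: 1.06,
    2018: 1.043,
    2019: 1.024,
    2020: 1.018,
    2021: 1.004,
    2022: 1.006,
    2023: 1.011,
}

_CPI_FIRST_BASE = min(HEALTHCARE_CPI) - 1  # 2014
_CPI_TARGET = max(HEALTHCARE_CPI)  # 2023


def cpi_adjust(cost: float, base_year: int) -> float:
    """Inflate a cost expressed in ``base_year`` CNY into 2023 CNY.

    Applies the cumulative product of the annual healthcare CPI factors for
    all calendar years strictly after ``base_year`` through 2023.
    """
    if cost < 0:
        raise ParameterValidationError(f"cost must be >= 0, got {cost!r}")
    if not _CPI_FIRST_BASE <= base_year <= _CPI_TARGET:
        raise ParameterValidationError(
            f"base_year {base_year} outside supported span "
            f"{_CPI_FIRST_BASE}-{_CPI_TARGET}"
        )
    factor = 1.0
    for year in range(base_year + 1, _CPI_TARGET + 1):
        factor *= HEALTHCARE_CPI[year]
    return cost * factor


# ---------------------------------------------------------------------------
# Drug cost
# ---------------------------------------------------------------------------


def tenecteplase_dose(weight: float, dose_per_kg: float = 0.25,
                      cap_mg: float = 25.0) -> float:
    """Weight-based tenecteplase dose in mg: 0.25 mg/kg capped at 25 mg."""
    if weight <= 0:
        raise ParameterValidationError(f"body weight must be > 0, got {weight!r}")
    return min(weight * dose_per_kg, cap_mg)


def tnk_drug_cost(weight: float, price_per_mg: float, iv_infusion: float = 0.0,
                  dose_per_kg: float = 0.25, cap_mg: float = 25.0) -> float:
    """Per-treatment tenecteplase cost: dose x unit price + IV infusion fee."""
    dose = tenecteplase_dose(weight, dose_per_kg=dose_per_kg, cap_mg=cap_mg)
    return dose * price_per_mg + iv_infusion


# ---------------------------------------------------------------------------
# Typed parameter blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MRSDistribution:
    """Probability vector over mRS 0-6 (mRS 6 = death), summing to one."""

    probs: np.ndarray

    def __init__(self, probs: Iterable[float], normalize: bool = False,
                 tol: float = 1e-9):
        p = np.asarray(list(probs), dtype=float)
        if p.shape != (N_MRS,):
            raise ParameterValidationError(
                f"mRS distribution needs {N_MRS} entries, got shape {p.shape}"
            )
        if np.any(p < 0):
            raise ParameterValidationError(
                f"mRS distribution has negative entries: {p}"
            )
        total = p.sum()
        if normalize:
            if total <= 0:
                raise ParameterValidationError(
                    "mRS distribution has zero total mass; cannot normalize"
                )
            p = p / total
        elif abs(total - 1.0) > tol:
            raise ParameterValidationError(
                f"mRS distribution sums to {total:.12f}, not 1"
            )
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    def __getitem__(self, i: int) -> float:
        return float(self.probs[i])

    @property
    def p_alive(self) -> float:
        return float(self.probs[:6].sum())

    def as_array(self) -> np.ndarray:
        return np.array(self.probs, dtype=float)


@dataclass(frozen=True)
class RiskRatioVector:
    """Per-mRS-category risk ratios (tenecteplase vs standard) with 95% CIs."""

    point: np.ndarray
    low: np.ndarray
    high: np.ndarray

    def __post_init__(self):
        for name in ("point", "low", "high"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_MRS,):
                raise ParameterValidationError(
                    f"risk-ratio {name} needs {N_MRS} entries"
                )
            object.__setattr__(self, name, arr)
        if np.any(self.point <= 0) or np.any(self.low <= 0):
            raise ParameterValidationError("risk ratios must be > 0")
        if np.any(self.low > self.point + 1e-12) or np.any(self.point > self.high + 1e-12):
            raise ParameterValidationError(
                "risk-ratio CI must satisfy low <= point <= high"
            )


@dataclass(frozen=True)
class UtilitySet:
    """Annual health-state utilities by mRS level, plus event (dis)utilities.

    ``u_mrs[6]`` (death) is fixed at zero. ``u_recurrence`` replaces the state
    utility for the cycle in which a survived recurrent stroke occurs;
    ``d_sich`` is the one-off utility decrement attached to a symptomatic
    intracranial hemorrhage in the acute phase.
    """

    u_mrs: np.ndarray  # length 7, u_mrs[6] == 0
    u_recurrence: float
    d_sich: float

    def __post_init__(self):
        u = np.asarray(self.u_mrs, dtype=float)
        if u.shape != (N_MRS,):
            raise ParameterValidationError(f"utilities need {N_MRS} entries")
        if abs(u[6]) > 1e-12:
            raise ParameterValidationError("utility of death (mRS 6) must be 0")
        if np.any(u < 0) or np.any(u > 1):
            raise ParameterValidationError("state utilities must lie in [0, 1]")
        # Utilities are non-increasing in mRS at the base case; one-way
        # sensitivity bounds (e.g. u_mrs1 -> 0.96) may cross a neighbour, so
        # monotonicity is not enforced here.
        if not 0 <= self.u_recurrence <= 1:
            raise ParameterValidationError("u_recurrence must lie in [0, 1]")
        if self.d_sich < 0:
            raise ParameterValidationError("d_sich must be >= 0")
        object.__setattr__(self, "u_mrs", u)


@dataclass(frozen=True)
class CostSet:
    """Unit costs in 2023 CNY."""

    acute_mrs01: float
    acute_mrs25: float
    acute_death: float
    sich_extra: float
    posthosp_mrs01: float
    posthosp_mrs25: float
    recurrent_stroke: float
    tnk_price_per_mg: float
    iv_infusion: float

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if value < 0:
                raise ParameterValidationError(f"cost {name} must be >= 0, got {value}")

    def acute_by_state(self) -> np.ndarray:
        """Acute-admission cost per month-3 mRS state (mRS 6 = in-hospital death)."""
        return np.array(
            [self.acute_mrs01] * 2 + [self.acute_mrs25] * 4 + [self.acute_death]
        )

    def posthosp_annual_by_state(self) -> np.ndarray:
        """Annual post-hospitalization care cost per mRS state (0 for death)."""
        return np.array(
            [self.posthosp_mrs01] * 2 + [self.posthosp_mrs25] * 4 + [0.0]
        )


@dataclass(frozen=True)
class EpidemiologyParams:
    """Recurrence risk, case fatality, and mortality structure."""

    annual_recurrence: float
    p_death_after_recurrence: float
    hr_mrs: np.ndarray  # length 6, hazard ratio on background mortality
    mortality_table: tuple[tuple[float, float | None, float], ...]

    def __post_init__(self):
        for name in ("annual_recurrence", "p_death_after_recurrence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterValidationError(f"{name} must lie in [0, 1], got {v}")
        hr = np.asarray(self.hr_mrs, dtype=float)
        if hr.shape != (6,):
            raise ParameterValidationError("hr_mrs needs 6 entries (mRS 0-5)")
        if np.any(hr < 1 - 1e-12):
            raise ParameterValidationError("mortality hazard ratios must be >= 1")
        # Non-decreasing in mRS at the base case; not enforced so that one-way
        # bounds (e.g. hr_mrs3 -> 1.02 with hr_mrs2 at 1.11) remain evaluable.
        object.__setattr__(self, "hr_mrs", hr)
        table = tuple(tuple(row) for row in self.mortality_table)
        if not table:
            raise ParameterValidationError("mortality table is empty")
        for i, (lo, hi, q) in enumerate(table):
            if not 0 <= q <= 1:
                raise ParameterValidationError(
                    f"mortality table row {i}: probability {q} outside [0, 1]"
                )
            if hi is not None and hi < lo:
                raise ParameterValidationError(
                    f"mortality table row {i}: band [{lo}, {hi}] inverted"
                )
            if i + 1 < len(table) and table[i + 1][0] != (hi + 1 if hi is not None else None):
                raise ParameterValidationError(
                    "mortality table bands must be contiguous"
                )
        if table[-1][1] is not None:
            raise ParameterValidationError(
                "last mortality band must be open-ended (85+)"
            )
        object.__setattr__(self, "mortality_table", table)

    def annual_mortality(self, age: float) -> float:
        """Annual background mortality probability for a given age.

        Ages below the first band reuse the first band's value (the published
        life table starts at the base-case cohort age); ages at or above the
        last band's lower bound use the open-ended band.
        """
        if age < 0:
            raise ParameterValidationError(f"age must be >= 0, got {age}")
        for lo, hi, q in self.mortality_table:
            if hi is None:
                if age >= lo:
                    return q
            elif age < hi + 1:
                return q
        return self.mortality_table[-1][2]


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration: cohort, horizon, discounting, dosing, thresholds."""

    start_age: float = 67.0
    horizon_years: float = 30.0
    cycle_length: float = 0.25
    n_markov_cycles: int = 119
    discount_rate: float = 0.05
    body_weight: float = 75.0
    dose_per_kg: float = 0.25
    dose_cap_mg: float = 25.0
    wtp_threshold: float = 89358.0
    half_cycle_correction: bool = True
    p_sich_tnk: float = 0.019
    p_sich_std: float = 0.008
    sich_disutility_absolute: bool = False
    discount_life_years: bool = True

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ParameterValidationError("discount_rate must be >= 0")
        if self.body_weight <= 0:
            raise ParameterValidationError("body_weight must be > 0")
        if self.cycle_length * (self.n_markov_cycles + 1) > self.horizon_years + self.cycle_length + 1e-9:
            raise ParameterValidationError(
                "cycle_length * (n_markov_cycles + 1) exceeds the horizon"
            )
        for name in ("p_sich_tnk", "p_sich_std"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterValidationError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Flat parameter registry and the aggregate ParameterSet
# ---------------------------------------------------------------------------

_MRS_KEYS = tuple(f"mrs3mo_std_{i}" for i in range(N_MRS))
_RR_KEYS = tuple(f"rr_mrs{i}" for i in range(N_MRS))
_HR_KEYS = tuple(f"hr_mrs{i}" for i in range(6))
_U_KEYS = tuple(f"u_mrs{i}" for i in range(6))

_COST_KEY_TO_FIELD = {
    "cost_acute_mrs01": "acute_mrs01",
    "cost_acute_mrs25": "acute_mrs25",
    "cost_acute_death": "acute_death",
    "cost_sich": "sich_extra",
    "cost_posthosp_mrs01": "posthosp_mrs01",
    "cost_posthosp_mrs25": "posthosp_mrs25",
    "cost_recurrent_stroke": "recurrent_stroke",
    "cost_tnk_per_mg": "tnk_price_per_mg",
    "cost_iv_infusion": "iv_infusion",
}

_CONFIG_KEYS = {
    "discount_rate": "discount_rate",
    "start_age": "start_age",
    "horizon_years": "horizon_years",
    "cycle_length": "cycle_length",
    "n_markov_cycles": "n_markov_cycles",
    "body_weight": "body_weight",
    "dose_per_kg": "dose_per_kg",
    "dose_cap_mg": "dose_cap_mg",
    "wtp_threshold": "wtp_threshold",
    "half_cycle_correction": "half_cycle_correction",
    "p_sich_tnk": "p_sich_tnk",
    "p_sich_std": "p_sich_std",
    "sich_disutility_absolute": "sich_disutility_absolute",
    "discount_life_years": "discount_life_years",
}


@dataclass(frozen=True)
class ParameterSet:
    """Fully validated bundle of every model input.

    Constructed from a flat name->value mapping (see the bundled defaults
    file). The flat names double as the handles used by the sensitivity
    analyses: :meth:`get` / :meth:`with_overrides` address any scalar input by
    its flat name, and :attr:`ranges` carries the published low/high bounds.
    """

    base_mrs: MRSDistribution
    risk_ratios: RiskRatioVector
    utilities: UtilitySet
    costs: CostSet
    epidemiology: EpidemiologyParams
    config: ModelConfig
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    psa_families: Mapping[str, str] = field(default_factory=dict)
    overrides: tuple[str, ...] = ()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_flat(cls, flat: Mapping[str, object],
                  ranges: Mapping[str, tuple[float, float]] | None = None,
                  psa_families: Mapping[str, str] | None = None,
                  overrides: Sequence[str] = ()) -> "ParameterSet":
        ranges = dict(ranges or {})
        missing = [k for k in (*_MRS_KEYS, *_RR_KEYS, *_HR_KEYS, *_U_KEYS,
                               "u_recurrence", "d_sich", "annual_recurrence",
                               "p_death_after_recurrence", "background_mortality",
                               *_COST_KEY_TO_FIELD) if k not in flat]
        if missing:
            raise ParameterValidationError(f"missing parameter(s): {missing}")

        base = MRSDistribution([float(flat[k]) for k in _MRS_KEYS], normalize=True)
        rr_point = [float(flat[k]) for k in _RR_KEYS]
        # CI bounds widen to include an overridden point (sensitivity probes
        # may push the point to, or past, a published bound).
        rr_low = [min(ranges.get(k, (rr_point[i], rr_point[i]))[0], rr_point[i])
                  for i, k in enumerate(_RR_KEYS)]
        rr_high = [max(ranges.get(k, (rr_point[i], rr_point[i]))[1], rr_point[i])
                   for i, k in enumerate(_RR_KEYS)]
        rr = RiskRatioVector(np.array(rr_point), np.array(rr_low), np.array(rr_high))
        util = UtilitySet(
            u_mrs=np.array([float(flat[k]) for k in _U_KEYS] + [0.0]),
            u_recurrence=float(flat["u_recurrence"]),
            d_sich=float(flat["d_sich"]),
        )
        costs = CostSet(**{fld: float(flat[key]) for key, fld in _COST_KEY_TO_FIELD.items()})
        epi = EpidemiologyParams(
            annual_recurrence=float(flat["annual_recurrence"]),
            p_death_after_recurrence=float(flat["p_death_after_recurrence"]),
            hr_mrs=np.array([float(flat[k]) for k in _HR_KEYS]),
            mortality_table=tuple(
                (row[0], row[1], row[2]) for row in flat["background_mortality"]
            ),
        )
        cfg_kwargs = {}
        for key, fld in _CONFIG_KEYS.items():
            if key in flat:
                v = flat[key]
                cfg_kwargs[fld] = v if isinstance(v, bool) else type(ModelConfig.__dataclass_fields__[fld].default)(v)
        config = ModelConfig(**cfg_kwargs)
        return cls(base_mrs=base, risk_ratios=rr, utilities=util, costs=costs,
                   epidemiology=epi, config=config, ranges=ranges,
                   psa_families=dict(psa_families or {}),
                   overrides=tuple(overrides))

    # -- flat access --------------------------------------------------------

    def to_flat(self) -> dict[str, object]:
        flat: dict[str, object] = {}
        for i, k in enumerate(_MRS_KEYS):
            flat[k] = float(self.base_mrs.probs[i])
        for i, k in enumerate(_RR_KEYS):
            flat[k] = float(self.risk_ratios.point[i])
        for i, k in enumerate(_HR_KEYS):
            flat[k] = float(self.epidemiology.hr_mrs[i])
        for i, k in enumerate(_U_KEYS):
            flat[k] = float(self.utilities.u_mrs[i])
        flat["u_recurrence"] = self.utilities.u_recurrence
        flat["d_sich"] = self.utilities.d_sich
        flat["annual_recurrence"] = self.epidemiology.annual_recurrence
        flat["p_death_after_recurrence"] = self.epidemiology.p_death_after_recurrence
        flat["background_mortality"] = [list(row) for row in self.epidemiology.mortality_table]
        for key, fld in _COST_KEY_TO_FIELD.items():
            flat[key] = getattr(self.costs, fld)
        for key, fld in _CONFIG_KEYS.items():
            flat[key] = getattr(self.config, fld)
        return flat

    def get(self, name: str) -> float:
        flat = self.to_flat()
        if name not in flat:
            raise KeyError(
                f"unknown parameter {name!r}; valid names: {sorted(flat)}"
            )
        return flat[name]

    def with_overrides(self, overrides: Mapping[str, object]) -> "ParameterSet":
        """Return a new validated set with the named scalars replaced.

        Overriding one mRS month-3 category rescales the other six
        proportionally so the distribution stays a distribution; all other
        names replace the value directly.
        """
        flat = self.to_flat()
        for name, value in overrides.items():
            if name not in flat:
                raise KeyError(
                    f"unknown parameter {name!r}; valid names: {sorted(flat)}"
                )
            if name in _MRS_KEYS:
                i = _MRS_KEYS.index(name)
                old = flat[name]
                new = float(value)
                if not 0 <= new < 1:
                    raise ParameterValidationError(
                        f"{name} must lie in [0, 1), got {new}"
                    )
                if old >= 1.0:
                    raise ParameterValidationError(
                        f"cannot rescale around {name} with mass {old}"
                    )
                scale = (1.0 - new) / (1.0 - old)
                for j, k in enumerate(_MRS_KEYS):
                    flat[k] = new if j == i else flat[k] * scale
            else:
                flat[name] = value
        return ParameterSet.from_flat(
            flat, ranges=self.ranges, psa_families=self.psa_families,
            overrides=tuple(sorted(set(self.overrides) | set(overrides))),
        )

    def ranged_parameters(self) -> list[str]:
        """Names of parameters carrying a published low/high range."""
        flat = self.to_flat()
        return [k for k in flat if k in self.ranges and not isinstance(flat[k], (list, bool))]

    def drug_cost(self) -> float:
        """Per-treatment tenecteplase cost under this configuration."""
        return tnk_drug_cost(
            self.config.body_weight, self.costs.tnk_price_per_mg,
            iv_infusion=self.costs.iv_infusion,
            dose_per_kg=self.config.dose_per_kg, cap_mg=self.config.dose_cap_mg,
        )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def _read_config_file(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParameterValidationError(
            f"config file {path} must contain a mapping of parameter names"
        )
    return data


def _default_flat() -> tuple[dict, dict, dict]:
    raw = yaml.safe_load(
        resources.files("strokecea.data").joinpath("table1_defaults.yaml").read_text()
    )
    flat, ranges, families = {}, {}, {}
    for key, entry in raw.items():
        if key == "background_mortality":
            flat[key] = entry
            continue
        if isinstance(entry, dict):
            flat[key] = entry["value"]
            if "range" in entry:
                ranges[key] = (float(entry["range"][0]), float(entry["range"][1]))
            if "dist" in entry:
                families[key] = entry["dist"]
        else:
            flat[key] = entry
    return flat, ranges, families


def load_parameters(config_file: str | Path | None = None,
                    overrides: Mapping[str, object] | None = None) -> ParameterSet:
    """Load the bundled base-case parameters, optionally overridden.

    Parameters
    ----------
    config_file:
        Optional YAML or JSON file of flat ``name: value`` overrides (or
        ``name: {value: ..., range: [lo, hi]}`` to also replace the
        sensitivity range).
    overrides:
        Programmatic overrides applied after the file, same semantics.
    """
    flat, ranges, families = _default_flat()
    applied: list[str] = []
    merged: dict[str, object] = dict(flat)

    def _apply(data: Mapping[str, object]):
        for key, entry in data.items():
            if key not in merged:
                raise ParameterValidationError(
                    f"unknown parameter {key!r} in overrides; "
                    f"valid names: {sorted(merged)}"
                )
            if isinstance(entry, dict) and "value" in entry:
                merged[key] = entry["value"]
                if "range" in entry:
                    ranges[key] = (float(entry["range"][0]), float(entry["range"][1]))
            else:
                merged[key] = entry
            applied.append(key)

    if config_file is not None:
        _apply(_read_config_file(config_file))
    if overrides:
        _apply(overrides)
    ps = ParameterSet.from_flat(merged, ranges=ranges, psa_families=families,
                                overrides=tuple(applied))
    # Range sanity: every published range must bracket its point value.
    for name in ps.ranged_parameters():
        lo, hi = ps.ranges[name]
        v = ps.get(name)
        if not (lo - 1e-9 <= v <= hi + 1e-9):
            raise ParameterValidationError(
                f"{name}: value {v} outside its range [{lo}, {hi}]"
            )
    return ps
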