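"""Probabilistic sensitivity analysis.

Each uncertain input is given a sampling distribution fitted by the method of
moments to its published point value and 95% interval: gamma for costs, beta
for probabilities and utilities, lognormal for risk and hazard ratios
(point value taken as the median), and a single Dirichlet for the month-3
mRS block whose effective sample size is calibrated so the mRS 0 marginal
reproduces its published interval. Draws are independent across inputs
except within the Dirichlet block; the tenecteplase month-3 distribution is
re-derived per draw from the sampled base distribution and risk ratios.

The Monte-Carlo loop evaluates the full decision-tree + Markov pipeline per
draw (vectorized over draws through the shared batched engine) and summarises
the incremental cost-effectiveness cloud, the classification histogram and
the cost-effectiveness acceptability curve. Randomness uses one master seed
with per-draw substreams, so extending the number of draws never changes
earlier draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markov import _BatchInputs, _run_markov_batch, classify
from .params import N_MRS, ParameterSet, tnk_drug_cost

QUARTER = 0.25
Z95 = 1.959963984540054  # two-sided 95% normal quantile

logger = logging.getLogger(__name__)

__all__ = [
    "PSADistributionSpec",
    "PSAResult",
    "CEACCurve",
    "fit_distribution",
    "fit_all_distributions",
    "dirichlet_alpha",
    "run_psa",
    "ceac",
]


@dataclass(frozen=True)
class PSADistributionSpec:
    """A fitted marginal sampling distribution for one input."""

    name: str
    family: str                   # gamma | beta | lognormal | point
    hyper: Mapping[str, float]
    mean: float
    low: float
    high: float

    def sample(self, rng: np.random.Generator, size=None):
        h = self.hyper
        if self.family == "point":
            return np.full(size, self.mean) if size else self.mean
        if self.family == "beta":
            return rng.beta(h["alpha"], h["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(h["shape"], h["scale"], size=size)
        if self.family == "lognormal":
            return rng.lognormal(h["mu"], h["sigma"], size=size)
        raise ValueError(f"unknown family {self.family!r}")

    def percentile(self, q: float) -> float:
        """Analytic quantile, used for round-trip checks against the range."""
        from scipy import stats

        h = self.hyper
        if self.family == "point":
            return self.mean
        if self.family == "beta":
            return float(stats.beta(h["alpha"], h["beta"]).ppf(q))
        if self.family == "gamma":
            return float(stats.gamma(h["shape"], scale=h["scale"]).ppf(q))
        if self.family == "lognormal":
            return float(stats.lognorm(h["sigma"], scale=math.exp(h["mu"])).ppf(q))
        raise ValueError(f"unknown family {self.family!r}")


def fit_distribution(name: str, family: str, mean: float, low: float,
                     high: float) -> PSADistributionSpec:
    """Method-of-moments fit from a point value and a 95% interval.

    The interval half-width is read as 1.96 standard deviations. Degenerate
    intervals give a point mass. For the lognormal the point value is the
    median (log-mean = ln(point)) and the log-sd comes from the interval on
    the log scale. Infeasible beta moments (sd too large for the support) are
    clipped to the largest feasible sd, with a logged warning.
    """
    if not low <= mean <= high:
        raise ValueError(f"{name}: need low <= mean <= high, got "
                         f"{low}, {mean}, {high}")
    sd = (high - low) / (2 * Z95)
    if sd == 0:
        return PSADistributionSpec(name, "point", {}, mean, low, high)

    if family == "beta":
        if not 0 < mean < 1:
            return PSADistributionSpec(name, "point", {}, mean, low, high)
        max_var = mean * (1 - mean)
        if sd ** 2 >= max_var:
            logger.warning(
                "%s: beta sd %.4g infeasible for mean %.4g; clipping", name, sd, mean
            )
            sd = 0.95 * math.sqrt(max_var)
        nu = max_var / sd ** 2 - 1
        hyper = {"alpha": mean * nu, "beta": (1 - mean) * nu}
    elif family == "gamma":
        if mean <= 0:
            return PSADistributionSpec(name, "point", {}, mean, low, high)
        hyper = {"shape": (mean / sd) ** 2, "scale": sd ** 2 / mean}
    elif family == "lognormal":
        if low <= 0:
            raise ValueError(f"{name}: lognormal needs a positive lower bound")
        hyper = {"mu": math.log(mean),
                 "sigma": (math.log(high) - math.log(low)) / (2 * Z95)}
    else:
        raise ValueError(f"{name}: unsupported family {family!r}")
    return PSADistributionSpec(name, family, hyper, mean, low, high)


def dirichlet_alpha(params: ParameterSet) -> np.ndarray | None:
    """Dirichlet concentration for the month-3 mRS block.

    The effective sample size N is calibrated so the mRS 0 marginal (a
    Beta(p0*N, (1-p0)*N) with variance p0(1-p0)/(N+1)) matches the published
    95% interval for that category. Returns ``None`` (a point mass) when the
    interval is degenerate.
    """
    p = params.base_mrs.as_array()
    lo, hi = params.ranges.get("mrs3mo_std_0", (p[0], p[0]))
    sd = (hi - lo) / (2 * Z95)
    if sd == 0:
        return None
    p0 = p[0]
    ess = p0 * (1 - p0) / sd ** 2 - 1
    return p * ess


def fit_all_distributions(params: ParameterSet) -> dict[str, PSADistributionSpec]:
    """Fitted marginals for every input carrying a PSA family (mRS block aside)."""
    specs = {}
    for name, family in params.psa_families.items():
        if family == "dirichlet":
            continue
        lo, hi = params.ranges[name]
        specs[name] = fit_distribution(name, family, params.get(name), lo, hi)
    return specs


# ---------------------------------------------------------------------------
# Monte-Carlo loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSAResult:
    """Per-draw increments and summary fractions from the Monte-Carlo loop."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    classification: np.ndarray   # per-draw decision label
    seed: int
    n_draws: int
    wtp_threshold: float

    @property
    def icer(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.delta_qaly != 0,
                            self.delta_cost / self.delta_qaly, np.nan)

    def quadrant_fractions(self) -> dict[str, float]:
        dc, dq = self.delta_cost, self.delta_qaly
        n = self.n_draws
        return {
            "NE (costlier, more effective)": float(((dc >= 0) & (dq > 0)).sum()) / n,
            "SE (cheaper, more effective)": float(((dc < 0) & (dq > 0)).sum()) / n,
            "SW (cheaper, less effective)": float(((dc < 0) & (dq <= 0)).sum()) / n,
            "NW (costlier, less effective)": float(((dc >= 0) & (dq <= 0)).sum()) / n,
        }

    def classification_fractions(self) -> dict[str, float]:
        labels, counts = np.unique(self.classification, return_counts=True)
        return {str(l): float(c) / self.n_draws for l, c in zip(labels, counts)}

    def fraction(self, label: str) -> float:
        return float((self.classification == label).sum()) / self.n_draws

    def fraction_below_wtp(self, wtp: float | None = None) -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        wtp = self.wtp_threshold if wtp is None else wtp
        return float((wtp * self.delta_qaly - self.delta_cost > 0).sum()) / self.n_draws

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "classification": self.classification,
        })


def _draw_parameters(params: ParameterSet, n_draws: int, seed: int) -> dict:
    """Sample all uncertain inputs; one substream per draw."""
    specs = fit_all_distributions(params)
    alpha = dirichlet_alpha(params)
    names = sorted(specs)
    scalars = np.empty((n_draws, len(names)))
    base = np.empty((n_draws, N_MRS))
    children = np.random.SeedSequence(seed).spawn(n_draws)
    point = params.base_mrs.as_array()
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        base[i] = point if alpha is None else rng.dirichlet(alpha)
        for j, name in enumerate(names):
            scalars[i, j] = specs[name].sample(rng)
    draws = {name: scalars[:, j] for j, name in enumerate(names)}
    draws["mrs3mo_std"] = base
    return draws


def run_psa(params: ParameterSet, n_draws: int = 10_000,
            seed: int = 2023) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Evaluates the full two-arm pipeline for ``n_draws`` sampled parameter
    sets and returns the per-draw increments with decision labels.
    Deterministic for a fixed seed and draw count.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    d = _draw_parameters(params, n_draws, seed)
    cfg = params.config
    B = n_draws

    base = d["mrs3mo_std"]                                   # (B, 7)
    rr = np.column_stack([d[f"rr_mrs{i}"] for i in range(N_MRS)])
    raw = base * rr
    tnk = raw / raw.sum(axis=1, keepdims=True)

    u_alive = np.column_stack([d[f"u_mrs{i}"] for i in range(6)])
    u7 = np.column_stack([u_alive, np.zeros(B)])
    acute = np.column_stack([
        d["cost_acute_mrs01"], d["cost_acute_mrs01"],
        d["cost_acute_mrs25"], d["cost_acute_mrs25"],
        d["cost_acute_mrs25"], d["cost_acute_mrs25"],
        d["cost_acute_death"],
    ])
    posthosp = np.column_stack([
        d["cost_posthosp_mrs01"], d["cost_posthosp_mrs01"],
        d["cost_posthosp_mrs25"], d["cost_posthosp_mrs25"],
        d["cost_posthosp_mrs25"], d["cost_posthosp_mrs25"],
    ])
    drug = np.array([
        tnk_drug_cost(cfg.body_weight, price, iv,
                      dose_per_kg=cfg.dose_per_kg, cap_mg=cfg.dose_cap_mg)
        for price, iv in zip(d["cost_tnk_per_mg"], d["cost_iv_infusion"])
    ])

    sich_factor = 1.0 if cfg.sich_disutility_absolute else QUARTER

    def tree(dist, p_sich, drug_cost):
        cost = (dist * acute).sum(axis=1) + p_sich * d["cost_sich"] + drug_cost
        qaly = (dist * u7).sum(axis=1) * QUARTER - p_sich * d["d_sich"] * sich_factor
        return cost, qaly

    cost_tree_std, qaly_tree_std = tree(base, d["p_sich_std"], 0.0)
    cost_tree_tnk, qaly_tree_tnk = tree(tnk, d["p_sich_tnk"], drug)

    inp = _BatchInputs(
        u_alive=u_alive,
        u_recurrence=d["u_recurrence"],
        posthosp_alive=posthosp,
        cost_recurrent=d["cost_recurrent_stroke"],
        p_rec=1.0 - (1.0 - d["annual_recurrence"]) ** 0.25,
        p_death_rec=d["p_death_after_recurrence"],
        hr=np.maximum(np.column_stack([d[f"hr_mrs{i}"] for i in range(6)]), 1.0),
        discount_rate=np.full(B, cfg.discount_rate),
        epi=params.epidemiology,
        start_age=cfg.start_age,
        n_cycles=cfg.n_markov_cycles,
        half_cycle_correction=cfg.half_cycle_correction,
    )
    mk_std = _run_markov_batch(base, inp)
    mk_tnk = _run_markov_batch(tnk, inp)

    delta_cost = (cost_tree_tnk + mk_tnk["cost"]) - (cost_tree_std + mk_std["cost"])
    delta_qaly = (qaly_tree_tnk + mk_tnk["qaly"]) - (qaly_tree_std + mk_std["qaly"])

    with np.errstate(divide="ignore", invalid="ignore"):
        icer = np.where(delta_qaly != 0, delta_cost / delta_qaly, np.nan)
    labels = np.array([
        classify(dc, dq, ic if np.isfinite(ic) else None, cfg.wtp_threshold)
        for dc, dq, ic in zip(delta_cost, delta_qaly, icer)
    ])
    return PSAResult(delta_cost=delta_cost, delta_qaly=delta_qaly,
                     classification=labels, seed=seed, n_draws=n_draws,
                     wtp_threshold=cfg.wtp_threshold)


# ---------------------------------------------------------------------------
# Acceptability curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CEACCurve:
    """Acceptability of each strategy over a willingness-to-pay grid."""

    wtp: np.ndarray
    p_tenecteplase: np.ndarray
    p_standard: np.ndarray
    crossover: float | None  # WTP where tenecteplase's acceptability crosses 0.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "wtp": self.wtp,
            "p_tenecteplase": self.p_tenecteplase,
            "p_standard": self.p_standard,
        })


def ceac(psa: PSAResult, wtp_grid: Sequence[float] | None = None) -> CEACCurve:
    """Cost-effectiveness acceptability curve and its 50% crossover.

    For each willingness-to-pay value the acceptability of tenecteplase is
    the fraction of draws with positive incremental net monetary benefit
    (``wtp * dQALY - dCost > 0``); the standard-care curve is its complement.
    The crossover is located by bracketing on the grid and linear
    interpolation; ``None`` when the curve never crosses 0.5 on the grid.
    """
    if psa.n_draws == 0:
        raise ValueError("empty draw table")
    grid = np.asarray(
        wtp_grid if wtp_grid is not None
        else np.arange(0, 100_001, 250), dtype=float,
    )
    nmb = grid[None, :] * psa.delta_qaly[:, None] - psa.delta_cost[:, None]
    p_tnk = (nmb > 0).mean(axis=0)
    crossover = None
    above = p_tnk >= 0.5
    if above.any() and not above[0]:
        j = int(np.argmax(above))
        x0, x1 = grid[j - 1], grid[j]
        y0, y1 = p_tnk[j - 1], p_tnk[j]
        crossover = float(x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0)) if y1 != y0 else float(x1)
    elif above.all():
        crossover = float(grid[0])
    return CEACCurve(wtp=grid, p_tenecteplase=p_tnk, p_standard=1.0 - p_tnk,
                     crossover=crossover)
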