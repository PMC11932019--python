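"""Synthetic two-arm RCT generator.

Emulates the statistical structure of the trial-derived model inputs: a
randomized trial with multinomial 90-day mRS outcomes in each arm and
binomial symptomatic-ICH counts, from which per-category risk ratios with
lognormal 95% confidence intervals are estimated. The resulting estimates
can be spliced into a parameter set in place of the published trial rows,
enabling end-to-end runs and parameter-recovery experiments without any
real trial data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .decision_tree import tnk_mrs_distribution
from .params import MRSDistribution, N_MRS, ParameterSet, RiskRatioVector

Z95 = 1.959963984540054

logger = logging.getLogger(__name__)

__all__ = ["SyntheticTrial", "simulate_trial", "trial_to_parameters"]


@dataclass(frozen=True)
class SyntheticTrial:
    """Observed counts and derived estimates from one simulated trial."""

    n_per_arm: int
    seed: int
    true_std: MRSDistribution
    true_tnk: MRSDistribution
    counts_std: np.ndarray        # (7,) 90-day mRS counts, standard arm
    counts_tnk: np.ndarray        # (7,)
    sich_std: int                 # sICH events, standard arm
    sich_tnk: int
    rr_point: np.ndarray          # (7,) estimated per-category risk ratios
    rr_low: np.ndarray
    rr_high: np.ndarray

    @property
    def p_std_hat(self) -> np.ndarray:
        return self.counts_std / self.n_per_arm

    @property
    def p_tnk_hat(self) -> np.ndarray:
        return self.counts_tnk / self.n_per_arm

    @property
    def p_sich_std_hat(self) -> float:
        return self.sich_std / self.n_per_arm

    @property
    def p_sich_tnk_hat(self) -> float:
        return self.sich_tnk / self.n_per_arm


def simulate_trial(true_std: MRSDistribution, true_rr: RiskRatioVector,
                   n_per_arm: int = 250, seed: int = 0,
                   p_sich_std: float = 0.008,
                   p_sich_tnk: float = 0.019) -> SyntheticTrial:
    """Simulate one two-arm trial and estimate the model's trial-derived rows.

    The tenecteplase arm's true outcome distribution is the base
    distribution reweighted by the true risk ratios (renormalized). Observed
    mRS counts are multinomial per arm; sICH counts are binomial. Risk
    ratios are estimated as the ratio of observed proportions with the
    standard two-proportion log-RR standard error
    ``sqrt(1/a - 1/n + 1/b - 1/n)``; any zero cell in a category triggers a
    0.5 continuity correction on both cells of that category (logged).
    """
    if n_per_arm < N_MRS:
        raise ValueError(f"n_per_arm must be >= {N_MRS}, got {n_per_arm}")
    true_tnk = tnk_mrs_distribution(true_std, true_rr)
    rng = np.random.default_rng(seed)
    counts_std = rng.multinomial(n_per_arm, true_std.as_array())
    counts_tnk = rng.multinomial(n_per_arm, true_tnk.as_array())
    sich_std = int(rng.binomial(n_per_arm, p_sich_std))
    sich_tnk = int(rng.binomial(n_per_arm, p_sich_tnk))

    a = counts_tnk.astype(float)
    b = counts_std.astype(float)
    n1 = np.full(N_MRS, float(n_per_arm))
    n2 = n1.copy()
    zero = (a == 0) | (b == 0)
    if zero.any():
        logger.info("continuity correction (0.5) applied in categories %s",
                    np.flatnonzero(zero).tolist())
        a = np.where(zero, a + 0.5, a)
        b = np.where(zero, b + 0.5, b)
        n1 = np.where(zero, n1 + 0.5, n1)
        n2 = np.where(zero, n2 + 0.5, n2)

    rr = (a / n1) / (b / n2)
    se_log = np.sqrt(1.0 / a - 1.0 / n1 + 1.0 / b - 1.0 / n2)
    rr_low = rr * np.exp(-Z95 * se_log)
    rr_high = rr * np.exp(Z95 * se_log)
    return SyntheticTrial(
        n_per_arm=n_per_arm, seed=seed, true_std=true_std, true_tnk=true_tnk,
        counts_std=counts_std, counts_tnk=counts_tnk,
        sich_std=sich_std, sich_tnk=sich_tnk,
        rr_point=rr, rr_low=rr_low, rr_high=rr_high,
    )


def _proportion_ci(k: int, n: int) -> tuple[float, float]:
    p = k / n
    half = Z95 * np.sqrt(max(p * (1 - p), 0.0) / n)
    return max(p - half, 0.0), min(p + half, 1.0)


def trial_to_parameters(trial: SyntheticTrial,
                        template: ParameterSet) -> ParameterSet:
    """Splice a simulated trial's estimates into a parameter set.

    Replaces the month-3 mRS distribution (standard arm), the per-category
    risk ratios with their estimated CIs, and the sICH probabilities; every
    other input is carried over from the template unchanged. The result
    passes full parameter validation and can be fed to any pipeline stage.
    """
    both_zero = (trial.counts_std == 0) & (trial.counts_tnk == 0)
    if both_zero.any():
        raise ValueError(
            f"categories {np.flatnonzero(both_zero).tolist()} have zero mass "
            "in both arms; increase n_per_arm or merge categories before "
            "building parameters"
        )
    flat = template.to_flat()
    ranges = dict(template.ranges)
    p_hat = trial.p_std_hat
    n = trial.n_per_arm
    for i in range(N_MRS):
        flat[f"mrs3mo_std_{i}"] = float(p_hat[i])
        ranges[f"mrs3mo_std_{i}"] = _proportion_ci(int(trial.counts_std[i]), n)
        flat[f"rr_mrs{i}"] = float(trial.rr_point[i])
        ranges[f"rr_mrs{i}"] = (float(trial.rr_low[i]), float(trial.rr_high[i]))
    flat["p_sich_std"] = trial.p_sich_std_hat
    ranges["p_sich_std"] = _proportion_ci(trial.sich_std, n)
    flat["p_sich_tnk"] = trial.p_sich_tnk_hat
    ranges["p_sich_tnk"] = _proportion_ci(trial.sich_tnk, n)
    return ParameterSet.from_flat(
        flat, ranges=ranges, psa_families=template.psa_families,
        overrides=tuple(sorted({*template.overrides, "synthetic_trial"})),
    )
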