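"""Short-term (first 3 months) decision tree.

The tree assigns each arm its expected acute-phase cost and QALYs over the
90-day trial window and produces the month-3 mRS distribution that seeds the
long-term Markov model. The tenecteplase arm's distribution is derived from
the standard-care distribution via the per-category risk ratios, renormalized
to sum to one, so that sensitivity draws of the risk ratios propagate
coherently into a valid distribution.

Acute-phase quantities are undiscounted (they fall in the first quarter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    MRSDistribution,
    ParameterSet,
    RiskRatioVector,
    tnk_drug_cost,
)

QUARTER = 0.25  # years

__all__ = ["ArmOutcome3mo", "tnk_mrs_distribution", "three_month_outcomes"]


@dataclass(frozen=True)
class ArmOutcome3mo:
    """Expected per-patient outcome of the first 3 months for one arm."""

    arm: str
    cost: float          # CNY, expected (acute admission + sICH + drug if any)
    qaly: float          # QALY over the 3-month window
    ly: float            # life-years over the 3-month window
    mrs_dist: MRSDistribution  # month-3 distribution seeding the Markov model


def tnk_mrs_distribution(base: MRSDistribution, rr: RiskRatioVector,
                         normalize: bool = True) -> MRSDistribution:
    """Month-3 mRS distribution in the tenecteplase arm.

    Element-wise product of the standard-care distribution with the
    per-category risk ratios. With ``normalize`` (default) the product is
    rescaled to sum to one; with the published point estimates the raw product
    sums to ~0.996, so the rescale is small.
    """
    raw = base.as_array() * np.asarray(rr.point, dtype=float)
    if raw.sum() <= 0:
        raise ValueError("risk ratios annihilate the base distribution")
    # unnormalized: relax the sum-to-one tolerance so the small deficit of the
    # raw product (~0.4% at the point estimates) is inspectable
    return MRSDistribution(raw, normalize=normalize,
                           tol=1e-9 if normalize else 0.05)


def _sich_qaly_loss(p_sich: float, d_sich: float, absolute: bool) -> float:
    """QALY decrement attributable to sICH in the acute window.

    Default convention treats ``d_sich`` as an annual utility decrement
    applied for the 3-month tree period (loss = p * d * 0.25); the absolute
    convention charges the full ``d_sich`` as a one-off QALY loss.
    """
    return p_sich * d_sich * (1.0 if absolute else QUARTER)


def three_month_outcomes(arm: str, params: ParameterSet) -> ArmOutcome3mo:
    """Expected first-3-month cost, QALYs and month-3 mRS state for one arm.

    Cost sums the mRS-class acute admission cost (mRS 0-1, mRS 2-5, death),
    the expected extra cost of sICH, and — in the tenecteplase arm — the
    weight-based drug cost plus infusion fee. QALYs credit each month-3 state
    its utility for the quarter (death contributes zero) minus the sICH
    disutility; life-years credit survivors the quarter.
    """
    cfg = params.config
    if arm == "standard":
        dist = params.base_mrs
        p_sich = cfg.p_sich_std
        drug = 0.0
    elif arm == "tenecteplase":
        dist = tnk_mrs_distribution(params.base_mrs, params.risk_ratios)
        p_sich = cfg.p_sich_tnk
        drug = tnk_drug_cost(
            cfg.body_weight, params.costs.tnk_price_per_mg,
            iv_infusion=params.costs.iv_infusion,
            dose_per_kg=cfg.dose_per_kg, cap_mg=cfg.dose_cap_mg,
        )
    else:
        raise ValueError(f"unknown arm {arm!r}; expected 'standard' or 'tenecteplase'")

    p = dist.as_array()
    cost = float(p @ params.costs.acute_by_state()) + p_sich * params.costs.sich_extra + drug
    qaly = float(p @ params.utilities.u_mrs) * QUARTER - _sich_qaly_loss(
        p_sich, params.utilities.d_sich, cfg.sich_disutility_absolute
    )
    ly = dist.p_alive * QUARTER
    return ArmOutcome3mo(arm=arm, cost=cost, qaly=qaly, ly=ly, mrs_dist=dist)
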