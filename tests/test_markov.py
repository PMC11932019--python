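"""Markov cohort engine: transitions, accumulation, discounting, comparison."""

import numpy as np
import pytest

from strokecea.decision_tree import three_month_outcomes
from strokecea.markov import (
    ArmResult,
    background_mortality_prob,
    compare_arms,
    cycle_transition,
    evaluate,
    redistribute_after_recurrence,
    run_cohort,
)
from strokecea.params import (
    MRSDistribution,
    ParameterSet,
    ParameterValidationError,
    annual_rate_to_cycle_prob,
)

QUARTER = 0.25


def _no_risk(params, **extra):
    """Parameter set with recurrence and background mortality switched off."""
    return params.with_overrides({
        "annual_recurrence": 0.0,
        "background_mortality": [[67, None, 0.0]],
        **extra,
    })


class TestRedistribution:
    @pytest.mark.parametrize("state, expected", [
        (5, [0, 0, 0, 0, 0, 1.0]),
        (3, [0, 0, 0, 1 / 3, 1 / 3, 1 / 3]),
        (0, [1 / 6] * 6),
    ])
    def test_uniform_over_same_or_worse(self, state, expected):
        np.testing.assert_allclose(redistribute_after_recurrence(state), expected)

    def test_dead_cannot_recur(self):
        with pytest.raises(ParameterValidationError):
            redistribute_after_recurrence(6)


class TestBackgroundMortality:
    def test_reference_values(self, params):
        epi = params.epidemiology
        assert background_mortality_prob(67, 0, epi) == pytest.approx(
            1 - (1 - 0.01266) ** 0.25, abs=1e-9)
        assert background_mortality_prob(67, 0, epi) == pytest.approx(0.003181, abs=2e-6)
        assert background_mortality_prob(67, 2, epi) == pytest.approx(0.003529, abs=2e-6)

    def test_open_ended_band(self, params):
        epi = params.epidemiology
        assert epi.annual_mortality(95) == 0.1512
        assert background_mortality_prob(95, 0, epi) == pytest.approx(
            1 - (1 - 0.1512) ** 0.25)

    def test_band_boundaries(self, params):
        epi = params.epidemiology
        assert epi.annual_mortality(69.75) == 0.01266
        assert epi.annual_mortality(70.0) == 0.02159
        assert epi.annual_mortality(84.99) == 0.0634
        assert epi.annual_mortality(85.0) == 0.1512

    def test_invalid_state(self, params):
        with pytest.raises(ParameterValidationError):
            background_mortality_prob(70, 6, params.epidemiology)


class TestCycleTransition:
    def test_probabilities_sum_to_one(self, params):
        for state in range(6):
            step = cycle_transition(state, 72.5, params)
            assert step.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(step.probs >= 0)

    def test_single_event_branching(self, params):
        # death probability = fatal recurrence + background death on the
        # no-recurrence branch
        step = cycle_transition(5, 67.25, params)
        p_rec = annual_rate_to_cycle_prob(0.112)
        bg = background_mortality_prob(67.25, 5, params.epidemiology)
        assert step.probs[6] == pytest.approx(p_rec * 0.21 + (1 - p_rec) * bg)

    def test_fatal_recurrence_probability(self, params):
        step = cycle_transition(0, 67.25, params)
        assert step.p_recurrence_death == pytest.approx(0.029259 * 0.21, abs=1e-5)
        assert step.p_recurrence_death == pytest.approx(0.006144, abs=2e-6)

    def test_identity_when_risks_zeroed(self, params):
        p = _no_risk(params)
        for state in range(6):
            step = cycle_transition(state, 70, p)
            expected = np.zeros(7)
            expected[state] = 1.0
            np.testing.assert_allclose(step.probs, expected, atol=1e-15)

    def test_dead_state_rejected(self, params):
        with pytest.raises(ParameterValidationError):
            cycle_transition(6, 70, params)


class TestRunCohort:
    def test_conservation_and_death_monotonicity(self, params):
        for arm in ("standard", "tenecteplase"):
            tree = three_month_outcomes(arm, params)
            res = run_cohort(tree.mrs_dist, params, collect_trace=True)
            occ = res.trace.occupancy
            np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
            dead = occ[:, 6]
            assert np.all(np.diff(dead) >= -1e-12)
            assert res.total_qaly <= res.total_ly + 1e-12

    def test_zero_risk_zero_discount_life_year_conservation(self, params):
        p = _no_risk(params, discount_rate=0.0)
        seed = MRSDistribution([1, 0, 0, 0, 0, 0, 0])
        res = run_cohort(seed, p, collect_trace=False)
        assert res.total_ly == pytest.approx(119 * QUARTER, abs=1e-9)
        assert res.total_qaly == pytest.approx(119 * QUARTER * 0.95, abs=1e-9)
        assert res.total_cost == pytest.approx(119 * QUARTER * 8867.0, rel=1e-12)

    def test_absorbing_seed_contributes_nothing(self, params):
        seed = MRSDistribution([0, 0, 0, 0, 0, 0, 1])
        res = run_cohort(seed, params, collect_trace=False)
        assert res.total_cost == 0.0
        assert res.total_qaly == 0.0
        assert res.total_ly == 0.0

    def test_invalid_seed_rejected(self, params):
        with pytest.raises(ParameterValidationError, match="sum"):
            from strokecea.markov import _batch_inputs, _run_markov_batch
            _run_markov_batch(np.array([[0.5, 0, 0, 0, 0, 0, 0]]),
                              _batch_inputs(params))

    def test_matrix_power_oracle_equivalence(self, params):
        """Engine totals must match an independent matrix-power evaluation.

        The oracle builds the per-cycle transition matrix state by state from
        cycle_transition, propagates the occupancy by matrix multiplication,
        and re-derives the trapezoidal accumulators from the documented
        conventions with scalar arithmetic.
        """
        p = params.with_overrides({"n_markov_cycles": 5})
        seed = np.array([0.3, 0.0, 0.2, 0.0, 0.0, 0.1, 0.4])
        cfg = p.config
        u = p.utilities.u_mrs
        u_rec = p.utilities.u_recurrence
        care = p.costs.posthosp_annual_by_state()
        p_rec = annual_rate_to_cycle_prob(p.epidemiology.annual_recurrence)
        p_dr = p.epidemiology.p_death_after_recurrence

        x = seed.copy()
        cost = qaly = ly = 0.0
        for k in range(1, 6):
            age = cfg.start_age + QUARTER * k
            T = np.zeros((7, 7))
            for s in range(6):
                T[s] = cycle_transition(s, age, p).probs
            T[6, 6] = 1.0
            x_new = x @ T
            mid = 0.5 * (x + x_new)
            events = x[:6].sum() * p_rec
            cost_k = QUARTER * float(mid @ care) + events * p.costs.recurrent_stroke
            corr = 0.0
            for s in range(6):
                m = x[s] * p_rec * (1 - p_dr)
                dest_u = float(redistribute_after_recurrence(s) @ u[:6])
                corr += m * (u_rec - 0.5 * (u[s] + dest_u))
            qaly_k = QUARTER * (float(mid @ u) + corr)
            ly_k = QUARTER * mid[:6].sum()
            df = (1 + cfg.discount_rate) ** (-QUARTER * k)
            cost += cost_k * df
            qaly += qaly_k * df
            ly += ly_k * df
            x = x_new

        res = run_cohort(MRSDistribution(seed), p, collect_trace=True)
        assert res.total_cost == pytest.approx(cost, abs=1e-10)
        assert res.total_qaly == pytest.approx(qaly, abs=1e-12)
        assert res.total_ly == pytest.approx(ly, abs=1e-12)
        np.testing.assert_allclose(res.trace.occupancy[-1], x, atol=1e-12)

    def test_discount_monotonicity(self, params):
        undiscounted = evaluate(params.with_overrides({"discount_rate": 0.0}))
        base = evaluate(params)
        for arm in ("standard", "tenecteplase"):
            a0 = getattr(undiscounted, arm)
            a5 = getattr(base, arm)
            assert a0.total_cost > a5.total_cost
            assert a0.total_qaly > a5.total_qaly
            assert a0.total_ly > a5.total_ly

    def test_hazard_ratio_lowers_life_years(self, params):
        seed = MRSDistribution([1, 0, 0, 0, 0, 0, 0])
        base = run_cohort(seed, params, collect_trace=False)
        worse = run_cohort(seed, params.with_overrides({"hr_mrs0": 1.2}),
                           collect_trace=False)
        assert worse.total_ly < base.total_ly


class TestCompareArms:
    @staticmethod
    def _arm(name, cost, qaly, ly=5.0):
        return ArmResult(arm=name, total_cost=cost, total_qaly=qaly,
                         total_ly=ly, total_ly_undisc=ly,
                         markov_cost=cost, markov_qaly=qaly)

    def test_reference_increments(self, params):
        res = compare_arms(self._arm("standard", 125229, 2.93),
                           self._arm("tenecteplase", 127765, 3.33),
                           params.config)
        assert res.icer == pytest.approx(2536 / 0.40)
        assert res.classification == "highly cost-effective"

    def test_identical_arms(self, params):
        res = compare_arms(self._arm("a", 100.0, 1.0), self._arm("b", 100.0, 1.0),
                           params.config)
        assert res.icer is None
        assert res.classification == "equivalent"

    def test_dominance_sign_logic(self, params):
        res = compare_arms(self._arm("a", 100.0, 1.0), self._arm("b", 99.0, 1.1),
                           params.config)
        assert res.classification == "dominant"
        res = compare_arms(self._arm("a", 100.0, 1.0), self._arm("b", 101.0, 0.9),
                           params.config)
        assert res.classification == "dominated"

    def test_gdp_multiple_bands(self, params):
        wtp = params.config.wtp_threshold
        res = compare_arms(self._arm("a", 0.0, 1.0),
                           self._arm("b", 2 * wtp, 2.0), params.config)
        assert res.classification == "cost-effective"
        res = compare_arms(self._arm("a", 0.0, 1.0),
                           self._arm("b", 4 * wtp, 2.0), params.config)
        assert res.classification == "not cost-effective"

    def test_arm_symmetry_under_unit_risk_ratios(self, params):
        p = params.with_overrides({f"rr_mrs{i}": 1.0 for i in range(7)}
                                  ).with_overrides({"p_sich_tnk": params.config.p_sich_std})
        res = evaluate(p)
        assert res.delta_qaly == pytest.approx(0.0, abs=1e-12)
        assert res.delta_cost == pytest.approx(p.drug_cost(), abs=1e-9)
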