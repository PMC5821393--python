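"""Cohort engine: matrix construction, projection, reward accrual and
discounting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sthpd_cea import (
    HealthState,
    ValidationError,
    build_transition_matrix,
    default_parameters,
    discounted_total,
    early_intervention_scenario,
    evaluate_scenario,
    project_cohort,
    usual_care_scenario,
)
from sthpd_cea.markov import cycle_rewards, discount_factors, state_cycle_values

PF, S, PD, DEAD = HealthState.PF, HealthState.STHPD, HealthState.PD, HealthState.DEAD


class TestTransitionMatrix:
    def test_usual_care_sthpd_row(self, params, usual_care):
        m = build_transition_matrix(params.transitions, usual_care)
        assert m[S] == pytest.approx([0.0815, 0.3120, 0.6037, 0.0028])

    def test_early_intervention_blends_risk_ratio(self, params, early_intervention):
        # u = 0.10, a = 0.70, RR = 0.538: p' = 0.6037 (1 - 0.07 * 0.462)
        m = build_transition_matrix(params.transitions, early_intervention)
        assert m[S, PD] == pytest.approx(0.58417634, abs=5e-9)
        assert m[S, S] == pytest.approx(0.33152366, abs=5e-9)

    def test_no_effect_reduction_reproduces_usual_care(self, params, usual_care):
        ei_zero = early_intervention_scenario(params, uptake=0.0)
        m_uc = build_transition_matrix(params.transitions, usual_care)
        m_zero = build_transition_matrix(params.transitions, ei_zero)
        assert np.array_equal(m_uc, m_zero)

    @pytest.mark.parametrize("scenario_name", ["usual_care", "early_intervention"])
    def test_structural_zeros_and_row_sums(self, params, usual_care,
                                           early_intervention, scenario_name):
        scen = usual_care if scenario_name == "usual_care" else early_intervention
        m = build_transition_matrix(params.transitions, scen)
        assert m[PF, PD] == 0.0 and m[PD, PF] == 0.0
        assert np.array_equal(m[DEAD], [0.0, 0.0, 0.0, 1.0])
        assert np.abs(m.sum(axis=1) - 1.0).max() < 1e-12
        assert ((m >= 0.0) & (m <= 1.0)).all()

    def test_death_identical_from_all_alive_states(self, params, early_intervention):
        m = build_transition_matrix(params.transitions, early_intervention)
        assert m[PF, DEAD] == m[S, DEAD] == m[PD, DEAD] == 0.0028


def _random_row_stochastic(rng):
    m = rng.random((4, 4))
    return m / m.sum(axis=1, keepdims=True)


class TestProjection:
    def test_one_cycle_mixed_occupancy(self, params, usual_care):
        # 0.46341 * 0.3120 + 0.53659 * 0.5214
        m = build_transition_matrix(params.transitions, usual_care)
        initial = np.array([0.0, 1.9 / 4.1, 2.2 / 4.1, 0.0])
        traj = project_cohort(initial, m, 1)
        assert traj[1, S] == pytest.approx(0.42436, abs=5e-6)

    def test_identity_matrix_constant_trajectory(self):
        initial = np.array([0.2, 0.3, 0.4, 0.1])
        traj = project_cohort(initial, np.eye(4), 7)
        assert np.array_equal(traj, np.tile(initial, (8, 1)))

    def test_dead_is_absorbing(self, params, usual_care):
        m = build_transition_matrix(params.transitions, usual_care)
        traj = project_cohort(np.array([0.0, 0.0, 0.0, 1.0]), m, 5)
        assert np.array_equal(traj[:, DEAD], np.ones(6))

    def test_agrees_with_stepwise_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1234)
        for _ in range(25):
            m = _random_row_stochastic(rng)
            initial = rng.dirichlet(np.ones(4))
            horizon = int(rng.integers(1, 12))
            traj = project_cohort(initial, m, horizon)
            vec = initial.copy()
            for t in range(1, horizon + 1):
                vec = np.array([vec @ m[:, j] for j in range(4)])
                assert np.abs(traj[t] - vec).max() < 1e-12

    @pytest.mark.parametrize("cohort", ["mixed", "sthpd_only"])
    @pytest.mark.parametrize("scenario_name", ["usual_care", "early_intervention"])
    def test_occupancy_conserved_and_death_monotone(
        self, params, usual_care, early_intervention, cohort, scenario_name
    ):
        from sthpd_cea import initial_occupancy

        scen = usual_care if scenario_name == "usual_care" else early_intervention
        m = build_transition_matrix(params.transitions, scen)
        traj = project_cohort(initial_occupancy(params.settings, cohort), m, 10)
        assert np.abs(traj.sum(axis=1) - 1.0).max() < 1e-12
        assert (np.diff(traj[:, DEAD]) >= 0).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            project_cohort(np.array([0.5, 0.5]), np.eye(4), 3)


class TestRewards:
    def test_pd_blended_utility_and_cost_usual_care(self, params, usual_care):
        utilities, costs = state_cycle_values(params, usual_care)
        assert utilities[PD] == pytest.approx(0.66849, abs=5e-6)
        assert costs[PD] == pytest.approx(18_739.414, abs=5e-3)

    def test_sthpd_values_early_intervention(self, params, early_intervention):
        utilities, costs = state_cycle_values(params, early_intervention)
        assert utilities[S] == pytest.approx(0.730 + 0.10 * 0.70 * 0.0655)
        assert costs[S] == pytest.approx(11_738.0 + 0.10 * 905.0)

    def test_zero_uptake_leaves_bare_state_values(self, params, usual_care):
        utilities, costs = state_cycle_values(params, usual_care)
        assert utilities[S] == pytest.approx(0.730)
        assert costs[S] == pytest.approx(11_738.0)

    def test_dead_contributes_nothing(self, params, early_intervention):
        utilities, costs = state_cycle_values(params, early_intervention)
        assert utilities[DEAD] == 0.0 and costs[DEAD] == 0.0

    def test_reward_stream_lengths_match_horizon(self, params, early_intervention):
        m = build_transition_matrix(params.transitions, early_intervention)
        traj = project_cohort(np.array([0.0, 1.0, 0.0, 0.0]), m, 5)
        stream = cycle_rewards(traj, params, early_intervention)
        assert stream.utility.shape == stream.cost.shape == (5,)
        assert ((stream.utility >= 0) & (stream.utility <= 1)).all()
        assert (stream.cost >= 0).all()


class TestDiscounting:
    @pytest.mark.parametrize(
        "rate, expected",
        [
            (0.0, 5.0),
            (0.04, 4.451822),   # sum of 1.04^-t, t = 1..5
            (0.015, 4.782645),  # sum of 1.015^-t, t = 1..5
        ],
    )
    def test_unit_stream_totals(self, rate, expected):
        assert discounted_total(np.ones(5), rate) == pytest.approx(expected, abs=5e-7)

    def test_rate_zero_equals_undiscounted_sum(self):
        rng = np.random.default_rng(0)
        values = rng.random(8)
        assert discounted_total(values, 0.0) == pytest.approx(values.sum())

    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=12))
    def test_monotone_decreasing_in_rate(self, values):
        values = np.asarray(values)
        totals = [discounted_total(values, r) for r in (0.0, 0.01, 0.05, 0.2)]
        assert all(a >= b - 1e-12 for a, b in zip(totals, totals[1:]))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            discounted_total(np.ones(3), -0.01)

    def test_start_timing_shifts_exponents(self):
        end = discount_factors(0.04, 3, "end")
        start = discount_factors(0.04, 3, "start")
        assert start[0] == 1.0
        assert np.allclose(start[1:], end[:-1])


class TestScenarioReduction:
    def test_zero_uptake_bit_identical_to_usual_care(self, params, usual_care):
        ei_zero = early_intervention_scenario(params, uptake=0.0)
        for cohort in ("mixed", "sthpd_only"):
            a = evaluate_scenario(params, usual_care, cohort)
            b = evaluate_scenario(params, ei_zero, cohort)
            assert a.qalys == b.qalys and a.cost == b.cost
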