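"""Cohort projection, discounting, shares, fold increase, microsimulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demcost import (
    DomainError,
    GeneratorConfig,
    SimulationConfig,
    cost_shares,
    fit_transition_model,
    fold_increase,
    generate_cohort,
    microsimulate,
    project_occupancy,
    scenario_matrix,
    select_analysis_sample,
    simulate_cohort,
    yearly_costs,
)
from conftest import INITIAL, P_EXAMPLE

SINK_SEVERE = np.array([[0, 0, 1], [0, 0, 1], [0, 0, 1.0]])


@st.composite
def stochastic_matrices(draw):
    rows = []
    for _ in range(3):
        weights = np.array(draw(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3)))
        rows.append(weights / weights.sum())
    return np.stack(rows)


@st.composite
def occupancies(draw):
    occ = np.array(draw(st.lists(st.floats(0.0, 2000.0), min_size=3, max_size=3)))
    return occ


class TestOccupancy:
    def test_identity_constant(self):
        occ = project_occupancy(np.eye(3), SimulationConfig(initial_occupancy=INITIAL))
        np.testing.assert_array_equal(occ, np.tile(INITIAL, (10, 1)))

    def test_severe_sink_absorbs_in_one_step(self):
        occ = project_occupancy(SINK_SEVERE, SimulationConfig(initial_occupancy=INITIAL))
        np.testing.assert_allclose(occ[1], [0, 0, 1341])

    def test_hand_matrix_vector_multiply(self):
        occ = project_occupancy(P_EXAMPLE, SimulationConfig(initial_occupancy=INITIAL))
        np.testing.assert_allclose(occ[1], [597.3, 426.2, 317.5])
        assert occ[1].sum() == pytest.approx(1341)

    def test_non_stochastic_rejected(self):
        with pytest.raises(DomainError):
            project_occupancy(np.full((3, 3), 0.5), SimulationConfig())

    @given(stochastic_matrices())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conservation_under_random_matrices(self, matrix):
        occ = project_occupancy(matrix, SimulationConfig(initial_occupancy=INITIAL))
        np.testing.assert_allclose(occ.sum(axis=1), 1341.0, rtol=1e-12)


class TestCosts:
    def test_year1_total_is_matrix_independent(self, default_schedule):
        config = SimulationConfig(initial_occupancy=INITIAL)
        for matrix in (np.eye(3), P_EXAMPLE, SINK_SEVERE):
            trajectory = simulate_cohort(matrix, default_schedule, config)
            assert trajectory.total_cost[0] == pytest.approx(67_294_910.94, abs=0.01)

    def test_zero_occupancy_zero_cost(self, default_schedule):
        config = SimulationConfig(initial_occupancy=(0, 0, 0))
        cost = yearly_costs(np.zeros((10, 3)), default_schedule, config)
        assert not cost.any()

    def test_present_value_one_period_identity(self, default_schedule):
        """An undiscounted year-2 cost of 105 becomes 100 at 5% present value."""
        config_pv = SimulationConfig(
            horizon_years=2, discount_mode="present_value", discount_rate=0.05
        )
        config_none = SimulationConfig(horizon_years=2, discount_mode="none")
        occ = np.ones((2, 3))
        ratio = (
            yearly_costs(occ, default_schedule, config_pv)[1]
            / yearly_costs(occ, default_schedule, config_none)[1]
        )
        np.testing.assert_allclose(ratio, 1 / 1.05)

    def test_compound_growth_inflates(self, default_schedule):
        config = SimulationConfig(horizon_years=3, discount_mode="compound_growth")
        occ = np.ones((3, 3))
        cost = yearly_costs(occ, default_schedule, config)
        np.testing.assert_allclose(cost[2] / cost[0], 1.05**2)

    @given(occupancies(), st.integers(0, 1), st.floats(0.1, 100.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_shifting_mass_to_worse_state_never_cheaper(
        self, default_schedule, occ, lower, delta
    ):
        """Monotone schedule: moving persons to a more severe state costs >=."""
        higher = lower + 1
        delta = min(delta, occ[lower])
        shifted = occ.copy()
        shifted[lower] -= delta
        shifted[higher] += delta
        config = SimulationConfig(horizon_years=1, discount_mode="none")
        base = yearly_costs(occ[None, :], default_schedule, config).sum()
        worse = yearly_costs(shifted[None, :], default_schedule, config).sum()
        assert worse >= base - 1e-6


class TestShares:
    def test_default_year1_shares(self, default_schedule):
        trajectory = simulate_cohort(P_EXAMPLE, default_schedule, SimulationConfig())
        assert round(trajectory.share[0, 0], 4) == 0.5064
        assert round(trajectory.share[0, 2], 4) == 0.1568

    def test_shares_sum_to_one(self, default_schedule):
        trajectory = simulate_cohort(P_EXAMPLE, default_schedule, SimulationConfig())
        np.testing.assert_allclose(trajectory.share.sum(axis=1), 1.0)

    def test_single_state_share_is_one(self, default_schedule):
        config = SimulationConfig(initial_occupancy=(0, 0, 144))
        trajectory = simulate_cohort(np.eye(3), default_schedule, config)
        assert trajectory.share[0, 2] == 1.0

    def test_zero_total_year_reported_missing(self):
        cost = np.zeros((2, 3))
        cost[0] = [1, 1, 2]
        share = cost_shares(cost)
        assert np.isnan(share[1]).all()
        np.testing.assert_allclose(share[0], [0.25, 0.25, 0.5])


class TestFoldIncrease:
    def test_identity_no_discount(self, default_schedule):
        config = SimulationConfig(discount_mode="none", initial_occupancy=INITIAL)
        trajectory = simulate_cohort(np.eye(3), default_schedule, config)
        assert fold_increase(trajectory.total_cost, 1) == 1.0
        assert fold_increase(trajectory.total_cost, 5) == pytest.approx(5.0)

    def test_three_step_brute_force(self, default_schedule):
        config = SimulationConfig(discount_mode="none", initial_occupancy=INITIAL)
        trajectory = simulate_cohort(P_EXAMPLE, default_schedule, config)
        totals = np.array([float(default_schedule.total[s]) for s in range(3)])
        occ = np.array(INITIAL)
        yearly = []
        for _ in range(3):
            yearly.append(occ @ totals)
            occ = occ @ P_EXAMPLE
        expected = sum(yearly) / yearly[0]
        assert fold_increase(trajectory.total_cost, 3) == pytest.approx(expected)

    def test_out_of_range_k(self, default_schedule):
        trajectory = simulate_cohort(np.eye(3), default_schedule, SimulationConfig())
        with pytest.raises(DomainError):
            fold_increase(trajectory.total_cost, 11)

    def test_cumulative_non_decreasing(self, default_schedule):
        trajectory = simulate_cohort(P_EXAMPLE, default_schedule, SimulationConfig())
        assert (np.diff(trajectory.cumulative_cost) >= 0).all()


class TestMicrosimulation:
    def test_identity_every_replicate_constant(self):
        config = SimulationConfig(initial_occupancy=(10, 5, 3), n_replicates=20, seed=1)
        sims = microsimulate(np.eye(3), config)
        assert (sims == np.array([10, 5, 3])).all()

    def test_same_seed_identical(self):
        config = SimulationConfig(initial_occupancy=INITIAL, n_replicates=5, seed=42)
        np.testing.assert_array_equal(
            microsimulate(P_EXAMPLE, config), microsimulate(P_EXAMPLE, config)
        )

    def test_conservation_each_replicate(self):
        config = SimulationConfig(initial_occupancy=INITIAL, n_replicates=50, seed=3)
        sims = microsimulate(P_EXAMPLE, config)
        assert (sims.sum(axis=2) == 1341).all()

    def test_mean_matches_deterministic_within_2pct(self):
        config = SimulationConfig(initial_occupancy=INITIAL, n_replicates=1000, seed=11)
        sims = microsimulate(P_EXAMPLE, config)
        deterministic = project_occupancy(P_EXAMPLE, config)
        np.testing.assert_allclose(sims.mean(axis=0), deterministic, rtol=0.02)

    def test_fractional_initial_rejected(self):
        config = SimulationConfig(initial_occupancy=(1.5, 2, 3))
        with pytest.raises(DomainError):
            microsimulate(P_EXAMPLE, config)


class TestScenarioBand:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_point_trajectory_between_directional_scenarios(
        self, default_schedule, seed
    ):
        records = generate_cohort(GeneratorConfig(seed=seed))
        pairs, _ = select_analysis_sample(records)
        model = fit_transition_model(pairs)
        config = SimulationConfig(discount_mode="none", initial_occupancy=INITIAL)
        point = simulate_cohort(model.point, default_schedule, config).total_cost
        pess = simulate_cohort(
            scenario_matrix(model, pessimistic=True), default_schedule, config
        ).total_cost
        opt = simulate_cohort(
            scenario_matrix(model, pessimistic=False), default_schedule, config
        ).total_cost
        assert (opt - 1e-6 <= point).all()
        assert (point <= pess + 1e-6).all()
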