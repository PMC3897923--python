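"""Cohort engine: propagation, accumulation, and its core invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tkawait import CohortModel, accumulate, propagate, run
from tkawait.engine import trace_to_frame
from tkawait.errors import ModelError
from tkawait.parameters import monthly_discount_factor


def two_state(p_death, horizon, cost=0.0, qaly=0.0, transition_rewards=None,
              start=(1.0, 0.0)):
    """Alive/dead model with constant monthly death probability."""
    P = np.array([[1 - p_death, p_death], [0.0, 1.0]])
    return CohortModel(
        states=["alive", "dead"],
        death_state="dead",
        transition=lambda t, age: P,
        cycle_rewards=np.array([[cost, qaly], [0.0, 0.0]]),
        start=np.array(start),
        start_age=60.0,
        horizon=horizon,
        transition_rewards=transition_rewards or {},
    )


class TestPropagate:
    def test_hand_computed_occupancy(self):
        trace = propagate(two_state(0.1, 3))
        np.testing.assert_allclose(trace.occupancy[:, 0], [1.0, 0.9, 0.81, 0.729])

    def test_identity_transitions_keep_occupancy(self):
        model = two_state(0.0, 5)
        trace = propagate(model)
        assert np.all(trace.occupancy[:, 0] == 1.0)

    def test_start_in_death_stays_absorbed(self):
        trace = propagate(two_state(0.1, 5, start=(0.0, 1.0)))
        assert np.all(trace.occupancy[:, 1] == 1.0)

    def test_flows_recorded_exactly(self):
        trace = propagate(two_state(0.25, 2), store_flows=True)
        np.testing.assert_allclose(trace.flows[0, 0, 1], 0.25)
        np.testing.assert_allclose(trace.flows[1, 0, 1], 0.75 * 0.25)

    def test_non_stochastic_row_names_cycle_and_row(self):
        P = np.array([[0.5, 0.4], [0.0, 1.0]])  # row 0 sums to 0.9
        model = two_state(0.1, 3)
        model.transition = lambda t, age: P
        with pytest.raises(ModelError, match="cycle 0.*row 0"):
            propagate(model)

    def test_trace_export_columns(self):
        model = two_state(0.1, 3)
        df = trace_to_frame(propagate(model), model)
        assert list(df.columns) == ["cycle", "age", "alive", "dead"]
        assert df["age"].iloc[1] == pytest.approx(60 + 1 / 12)


class TestAccumulate:
    def test_geometric_series_oracle_undiscounted(self):
        # u = 0.6/yr, monthly survival s: QALYs = (0.6/12) * 1/(1-s)
        q = 1 - 0.88 ** (1 / 12)
        model = two_state(q, 5000, qaly=0.6 / 12)
        result = run(model, 0.0)
        s = 1 - q
        assert result.qalys == pytest.approx((0.6 / 12) / (1 - s), abs=1e-9)
        assert result.qalys == pytest.approx(0.05 / (1 - s), abs=1e-9)

    @given(st.floats(0.002, 0.05), st.floats(0.0, 0.10), st.floats(0.1, 1.0))
    def test_constant_hazard_discounted_oracle(self, q_m, r, u):
        # discounted QALYs = (u/12) / (1 - (1-q_m) v) for a 2-state model
        model = two_state(q_m, 20_000, qaly=u / 12)
        v = monthly_discount_factor(r)
        expected = (u / 12) / (1 - (1 - q_m) * v)
        assert run(model, r).qalys == pytest.approx(expected, abs=1e-9)

    def test_all_zero_rewards(self):
        result = run(two_state(0.1, 10), 0.03)
        assert result.cost == 0.0 and result.qalys == 0.0

    def test_one_time_reward_scales_with_flow_mass(self):
        model = two_state(0.5, 1, transition_rewards={("alive", "dead"): (0.0, -0.1)})
        result = run(model, 0.0)
        assert result.qalys == pytest.approx(-0.05)

    def test_one_time_reward_discounted_at_flow_cycle(self):
        model = two_state(1.0, 1, transition_rewards={("alive", "dead"): (100.0, 0.0)})
        v = monthly_discount_factor(0.03)
        assert run(model, 0.03).cost == pytest.approx(100 * v)

    def test_cost_linearity(self):
        m1 = two_state(0.02, 200, cost=10.0)
        m2 = two_state(0.02, 200, cost=20.0)
        assert run(m2, 0.03).cost == pytest.approx(2 * run(m1, 0.03).cost, rel=1e-12)

    def test_horizon_one_cycle(self):
        result = run(two_state(0.5, 1, qaly=1.0), 0.0)
        assert result.qalys == 1.0  # first cycle only, full start occupancy

    def test_half_cycle_correction_averages_occupancy(self):
        model = two_state(0.5, 1, qaly=1.0)
        full = run(model, 0.0)
        half = run(model, 0.0, half_cycle=True)
        assert half.qalys == pytest.approx(0.75)  # (1 + 0.5) / 2
        assert half.qalys < full.qalys

    def test_discount_monotonicity(self):
        model = two_state(0.01, 2000, cost=5.0, qaly=0.05)
        totals = [run(model, r) for r in (0.0, 0.01, 0.03, 0.08)]
        costs = [t.cost for t in totals]
        qalys = [t.qalys for t in totals]
        assert costs == sorted(costs, reverse=True)
        assert qalys == sorted(qalys, reverse=True)
        assert totals[1].cost <= totals[0].cost_undiscounted

    def test_horizon_convergence_after_absorption(self):
        a = run(two_state(0.1, 400, qaly=0.05), 0.0)
        b = run(two_state(0.1, 4000, qaly=0.05), 0.0)
        assert abs(a.qalys - b.qalys) < 1e-12

    def test_qalys_bounded_by_life_years(self):
        result = run(two_state(0.01, 3000, qaly=0.9 / 12), 0.0)
        assert result.qalys <= result.life_years


@st.composite
def random_models(draw):
    n = draw(st.integers(2, 5))
    horizon = draw(st.integers(1, 40))
    raw = draw(
        st.lists(
            st.lists(st.floats(0.0, 1.0), min_size=n, max_size=n),
            min_size=n - 1, max_size=n - 1,
        )
    )
    P = np.ones((n, n))
    for i, row in enumerate(raw):
        r = np.asarray(row) + 1e-9
        P[i] = r / r.sum()
    P[n - 1] = 0.0
    P[n - 1, n - 1] = 1.0
    start = np.zeros(n)
    start[draw(st.integers(0, n - 1))] = 1.0
    states = [f"s{i}" for i in range(n - 1)] + ["dead"]
    rewards = np.zeros((n, 2))
    rewards[: n - 1, 0] = draw(st.floats(0.0, 100.0))
    rewards[: n - 1, 1] = draw(st.floats(0.0, 0.1))
    return CohortModel(
        states=states, death_state="dead", transition=lambda t, age: P,
        cycle_rewards=rewards, start=start, start_age=60.0, horizon=horizon,
    )


class TestEngineInvariants:
    @given(random_models())
    def test_mass_conserved_and_death_monotone(self, model):
        trace = propagate(model)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        death = trace.occupancy[:, model.death_index]
        assert np.all(np.diff(death) >= -1e-12)

    @given(random_models())
    def test_discounted_below_undiscounted(self, model):
        result = run(model, 0.05)
        assert result.cost <= result.cost_undiscounted + 1e-9
        assert result.qalys <= result.qalys_undiscounted + 1e-9
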