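"""Discrete-time Markov cohort engine.

Propagates a cohort's state-occupancy distribution through monthly cycles
under a (possibly time-varying) row-stochastic transition matrix, and
accumulates discounted costs and QALYs from per-cycle state rewards plus
one-time rewards attached to specific transitions (procedure costs, recovery
disutilities).

Conventions
-----------
* ``occupancy[t]`` is the distribution at the *start* of cycle ``t``;
  per-cycle rewards accrue on start-of-cycle occupancy for the full cycle
  (no half-cycle correction unless requested).
* The flow from cycle ``t`` to ``t+1`` realises its one-time rewards at the
  start of cycle ``t+1`` and is discounted accordingly; entry rewards on the
  starting distribution are undiscounted.
* Discounting compounds per cycle at ``(1+r)**(-1/12)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import ModelError
from .parameters import CYCLES_PER_YEAR, monthly_discount_factor

#: alive-mass threshold below which the cohort counts as fully absorbed
ABSORPTION_TOL = 1e-12

#: maximum state count for which dense per-cycle flows are stored by default
_DENSE_FLOW_STATES = 16

TransitionRule = Callable[[int, float], np.ndarray]


@dataclass
class CohortModel:
    """One strategy's state space, transition rule and reward structure.

    ``transition(cycle, age_years)`` must return a row-stochastic matrix over
    ``states``; ``death_state`` is absorbing. ``cycle_rewards`` holds per-cycle
    (cost $, QALY) per state; ``transition_rewards`` maps (from, to) state-name
    pairs to one-time (cost $, QALY) applied to the flow mass making that
    transition; ``entry_rewards`` maps states to one-time rewards applied to
    the starting distribution (e.g. surgery at cycle 0).
    """

    states: list[str]
    death_state: str
    transition: TransitionRule
    cycle_rewards: np.ndarray  # (n_states, 2): cost $/cycle, QALY/cycle
    start: np.ndarray  # (n_states,)
    start_age: float
    horizon: int
    transition_rewards: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    entry_rewards: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cycle_rewards = np.asarray(self.cycle_rewards, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        n = len(self.states)
        if self.death_state not in self.states:
            raise ModelError(f"death state {self.death_state!r} not in state list")
        if self.cycle_rewards.shape != (n, 2):
            raise ModelError(f"cycle_rewards shape {self.cycle_rewards.shape} != ({n}, 2)")
        if self.start.shape != (n,):
            raise ModelError(f"start distribution shape {self.start.shape} != ({n},)")
        if abs(self.start.sum() - 1.0) > 1e-12 or np.any(self.start < 0):
            raise ModelError("start distribution must be a probability vector")
        if self.horizon < 1:
            raise ModelError(f"horizon {self.horizon} must be >= 1")
        for pair in self.transition_rewards:
            for s in pair:
                if s not in self.states:
                    raise ModelError(f"transition reward names unknown state {s!r}")
        for s in self.entry_rewards:
            if s not in self.states:
                raise ModelError(f"entry reward names unknown state {s!r}")
        self._index = {s: i for i, s in enumerate(self.states)}

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def death_index(self) -> int:
        return self._index[self.death_state]

    def state_index(self, state: str) -> int:
        return self._index[state]


@dataclass
class CohortTrace:
    """Occupancy and transition flows from one propagation.

    ``occupancy`` has ``n_cycles + 1`` rows (start of each cycle plus the
    final distribution). ``reward_flows[(i, j)][t]`` is the mass flowing
    ``i -> j`` between cycles ``t`` and ``t+1`` for every pair carrying a
    one-time reward; ``flows`` is the full dense (cycle, from, to) array and
    is stored only for small state spaces or on request.
    """

    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    reward_flows: dict[tuple[int, int], np.ndarray]
    flows: np.ndarray | None = None

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


@dataclass(frozen=True)
class RunResult:
    """Lifetime totals for one strategy run."""

    cost: float  # discounted $
    qalys: float  # discounted QALY
    cost_undiscounted: float
    qalys_undiscounted: float
    life_years: float  # undiscounted expected years alive
    trace: CohortTrace | None = None


def _validate_matrix(P: np.ndarray, n: int, death: int, cycle: int) -> None:
    if P.shape != (n, n):
        raise ModelError(f"cycle {cycle}: transition matrix shape {P.shape} != ({n}, {n})")
    if np.any(P < 0):
        row = int(np.argwhere(P < 0)[0, 0])
        raise ModelError(f"cycle {cycle}: negative entry in row {row} ({P[row]})")
    sums = P.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-12)
    if bad.size:
        row = int(bad[0])
        raise ModelError(f"cycle {cycle}: row {row} sums to {sums[row]!r}, not 1")
    death_row = np.zeros(n)
    death_row[death] = 1.0
    if not np.array_equal(P[death], death_row):
        raise ModelError(f"cycle {cycle}: death row is not absorbing")


def propagate(model: CohortModel, store_flows: bool | None = None) -> CohortTrace:
    """Run the cohort forward, recording occupancy and reward-bearing flows.

    Stops early once the living mass falls below ``ABSORPTION_TOL`` provided
    the absorbing state carries no rewards (always true here).
    """
    n = model.n_states
    death = model.death_index
    if store_flows is None:
        store_flows = n <= _DENSE_FLOW_STATES
    pairs = [(model.state_index(a), model.state_index(b)) for a, b in model.transition_rewards]

    occ = [model.start.copy()]
    flow_rows: dict[tuple[int, int], list[float]] = {p: [] for p in pairs}
    dense: list[np.ndarray] = []
    death_rewards_zero = np.all(model.cycle_rewards[death] == 0.0)

    for t in range(model.horizon):
        cur = occ[-1]
        alive = 1.0 - cur[death]
        if death_rewards_zero and alive < ABSORPTION_TOL:
            break
        age = model.start_age + t / CYCLES_PER_YEAR
        P = np.asarray(model.transition(t, age), dtype=float)
        _validate_matrix(P, n, death, t)
        nxt = cur @ P
        for p in pairs:
            flow_rows[p].append(cur[p[0]] * P[p])
        if store_flows:
            dense.append(cur[:, None] * P)
        occ.append(nxt)

    return CohortTrace(
        occupancy=np.asarray(occ),
        reward_flows={p: np.asarray(v) for p, v in flow_rows.items()},
        flows=np.asarray(dense) if store_flows else None,
    )


def accumulate(
    trace: CohortTrace,
    model: CohortModel,
    discount_annual: float,
    half_cycle: bool = False,
) -> RunResult:
    """Fold a trace into discounted lifetime cost and QALY totals.

    With ``half_cycle=True`` per-cycle rewards accrue on the average of the
    start- and end-of-cycle occupancy (the classic half-cycle correction);
    one-time transition rewards are unaffected.
    """
    n_cycles = trace.n_cycles
    if trace.occupancy.shape[1] != model.n_states:
        raise ModelError(
            f"trace has {trace.occupancy.shape[1]} states, model has {model.n_states}"
        )
    missing = [
        pair for pair in model.transition_rewards
        if (model.state_index(pair[0]), model.state_index(pair[1])) not in trace.reward_flows
    ]
    if missing and trace.flows is None:
        raise ModelError(f"trace lacks flows for reward pairs {missing}")

    v = monthly_discount_factor(discount_annual)
    disc = v ** np.arange(n_cycles + 1)

    if half_cycle:
        occ_eff = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])
    else:
        occ_eff = trace.occupancy[:-1]
    per_cycle = occ_eff @ model.cycle_rewards  # (n_cycles, 2)
    cost = float(per_cycle[:, 0] @ disc[:n_cycles])
    qalys = float(per_cycle[:, 1] @ disc[:n_cycles])
    cost_u = float(per_cycle[:, 0].sum())
    qalys_u = float(per_cycle[:, 1].sum())

    for (a, b), (r_cost, r_qaly) in model.transition_rewards.items():
        pair = (model.state_index(a), model.state_index(b))
        flow = trace.reward_flows.get(pair)
        if flow is None:
            flow = trace.flows[:, pair[0], pair[1]]
        # flow t -> realised at start of cycle t+1
        w = disc[1:len(flow) + 1]
        cost += r_cost * float(flow @ w)
        qalys += r_qaly * float(flow @ w)
        cost_u += r_cost * float(flow.sum())
        qalys_u += r_qaly * float(flow.sum())

    for state, (r_cost, r_qaly) in model.entry_rewards.items():
        mass = trace.occupancy[0, model.state_index(state)]
        cost += r_cost * mass
        qalys += r_qaly * mass
        cost_u += r_cost * mass
        qalys_u += r_qaly * mass

    alive = 1.0 - trace.occupancy[:-1, model.death_index]
    life_years = float(alive.sum()) / CYCLES_PER_YEAR

    return RunResult(cost, qalys, cost_u, qalys_u, life_years, trace)


def run(model: CohortModel, discount_annual: float, half_cycle: bool = False) -> RunResult:
    """Propagate then accumulate — the one-call interface."""
    trace = propagate(model)
    return accumulate(trace, model, discount_annual, half_cycle=half_cycle)


def trace_to_frame(trace: CohortTrace, model: CohortModel):
    """Occupancy trace as a DataFrame: cycle, cohort age, one column per state."""
    import pandas as pd

    n_rows = trace.occupancy.shape[0]
    ages = model.start_age + np.arange(n_rows) / CYCLES_PER_YEAR
    df = pd.DataFrame(trace.occupancy, columns=model.states)
    df.insert(0, "age", ages)
    df.insert(0, "cycle", np.arange(n_rows))
    return df
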