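"""The three treatment strategies as cohort models.

A 60-year-old cohort with end-stage knee osteoarthritis either receives a
total knee arthroplasty (TKA) immediately, waits for it untreated, or waits
on a non-operative bridge (injections, therapy, NSAIDs) that partially
relieves symptoms. After surgery the implant can fail and be revised, at
annual rates that rise with implant age (tiers 0-9 / 10-19 / 20+ years, no
failures in the first implant year); at most two revisions are modelled.
Each surgery month carries an excess 30-day mortality on top of background
life-table mortality.

Implant age is tracked exactly: the primary implant's age is the global
cycle clock offset by the (deterministic) surgery month, while first-revision
implants — whose surgery dates are spread over the cohort — get explicit
monthly tunnel states up to the 20-year tier, beyond which the hazard is
constant. Second revisions cannot fail again, so they need no clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import CohortModel, RunResult, run
from .errors import ValidationError
from .parameters import (
    CYCLES_PER_YEAR,
    STRATEGIES,
    LifeTable,
    ParameterSet,
    annual_to_monthly_prob,
)

#: months of tunnel resolution for first-revision implants (20 years; the
#: failure hazard is constant beyond the last tier boundary)
_TUNNEL_MONTHS = 240


@dataclass(frozen=True)
class StrategySpec:
    """A strategy identifier bound to its parameters and life table."""

    strategy: str
    params: ParameterSet
    life_table: LifeTable

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )

    @property
    def wait_months(self) -> int:
        """Effective wait (immediate surgery ignores the configured wait)."""
        return 0 if self.strategy == "immediate_tka" else int(self.params.wait_months)

    @property
    def has_bridge(self) -> bool:
        return self.strategy == "delay_bridge"


def combine_risks(p1: float, p2: float) -> float:
    """Independent competing monthly risks: ``1 - (1-p1)(1-p2)``."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p!r} outside [0, 1]")
    return 1.0 - (1.0 - p1) * (1.0 - p2)


def revision_monthly_prob(
    implant_age_months: int, tiers: tuple[float, float, float]
) -> float:
    """Monthly implant-failure probability at a given implant age.

    No failures before 12 months; annual tier probabilities apply on
    half-open year intervals [0, 10), [10, 20), [20, inf).
    """
    if implant_age_months < 12:
        return 0.0
    if implant_age_months < 120:
        p = tiers[0]
    elif implant_age_months < _TUNNEL_MONTHS:
        p = tiers[1]
    else:
        p = tiers[2]
    return annual_to_monthly_prob(p)


# --------------------------------------------------------------------------
# rewards

_CANONICAL_STATES = (
    "WAIT", "WAIT_LATE", "POST_TKA", "WELL_TKA",
    "POST_REV1", "WELL_REV1", "POST_REV2", "WELL_REV2", "DEAD",
)


def strategy_rewards(state: str, spec: StrategySpec) -> tuple[float, float]:
    """Annual (cost $, utility QALY) accrual for one canonical state.

    Scenario A counts direct medical costs only (bridge treatment, surgery
    episodes); scenario B adds the indirect costs of knee OA, of which a
    fraction (80% in the base case) is recovered after successful surgery.
    One-time rewards (surgery costs, recovery disutilities) are returned by
    :func:`one_time_rewards`, not here.
    """
    p = spec.params
    indirect = p.scenario == "B"
    residual = (1.0 - p.indirect_recovery_fraction) * p.c_indirect_oa_annual
    if state in ("WAIT", "WAIT_LATE"):
        cost = p.c_indirect_oa_annual if indirect else 0.0
        if spec.has_bridge:
            cost += p.c_bridge_annual
        util = p.u_oa
        if state == "WAIT" and spec.has_bridge:
            util = p.bridge_wait_utility
        return cost, util
    if state in ("POST_TKA", "WELL_TKA"):
        return (residual if indirect else 0.0), p.u_tka
    if state in ("POST_REV1", "WELL_REV1", "POST_REV2", "WELL_REV2"):
        return (residual if indirect else 0.0), p.u_rev
    if state == "DEAD":
        return 0.0, 0.0
    raise ValueError(f"unknown state {state!r}; expected one of {_CANONICAL_STATES}")


def one_time_rewards(spec: StrategySpec) -> dict[str, tuple[float, float]]:
    """One-time ($, QALY) rewards charged on surgery transitions.

    The primary-surgery entry also carries the expected early-complication
    disutility (probability x one-time QALY loss) when complications are
    enabled; complications change no state (the surgery episode cost already
    covers 90 days of care, including complication treatment).
    """
    p = spec.params
    comp = (
        p.p_early_complication * p.dis_complication
        if p.include_complications
        else 0.0
    )
    return {"tka": (p.c_tka, comp), "revision": (p.c_rev, p.dis_rev)}


# --------------------------------------------------------------------------
# model construction


def build_strategy(spec: StrategySpec) -> CohortModel:
    """Assemble the cohort model for one strategy.

    Delayed strategies occupy the wait state for ``wait_months`` cycles under
    background mortality only, then flow into the one-month post-surgery
    state; with ``wait_months == 0`` every strategy starts directly in the
    post-surgery state, so the zero-wait delay degenerates to immediate
    surgery exactly.
    """
    p = spec.params
    lt = spec.life_table
    W = spec.wait_months

    # relief phase: months of the wait spent at the bridge utility
    if spec.has_bridge and p.bridge_relief_months is not None:
        relief = min(int(p.bridge_relief_months), W)
    else:
        relief = W

    tunnel = [f"WELL_REV1_M{k}" for k in range(1, _TUNNEL_MONTHS)]
    states = (
        ["WAIT", "WAIT_LATE", "POST_TKA", "WELL_TKA", "POST_REV1"]
        + tunnel
        + ["WELL_REV1_LATE", "POST_REV2", "WELL_REV2", "DEAD"]
    )
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    WAIT, WAIT_LATE = idx["WAIT"], idx["WAIT_LATE"]
    POST_TKA, WELL_TKA = idx["POST_TKA"], idx["WELL_TKA"]
    POST_REV1, R1_LATE = idx["POST_REV1"], idx["WELL_REV1_LATE"]
    POST_REV2, WELL_REV2, DEAD = idx["POST_REV2"], idx["WELL_REV2"], idx["DEAD"]
    t0 = idx["WELL_REV1_M1"]

    # 30-day risks apply wholly within the one-month procedure state
    p30p = p.p_mort30_primary
    p30r = p.p_mort30_revision

    # static per-state revision hazards (revision-implant tiers)
    rev_haz = np.zeros(n)
    for k in range(1, _TUNNEL_MONTHS):
        rev_haz[t0 + k - 1] = revision_monthly_prob(k, p.p_rev_revision_by_tier)
    rev_haz[R1_LATE] = revision_monthly_prob(_TUNNEL_MONTHS, p.p_rev_revision_by_tier)

    # static survivor destinations (WAIT/WELL_TKA handled per cycle)
    nxt = np.arange(n)
    nxt[POST_TKA] = WELL_TKA
    nxt[POST_REV1] = t0
    for k in range(1, _TUNNEL_MONTHS - 1):
        nxt[t0 + k - 1] = t0 + k
    nxt[t0 + _TUNNEL_MONTHS - 2] = R1_LATE
    nxt[R1_LATE] = R1_LATE
    nxt[WELL_REV2] = WELL_REV2

    rev_dest = np.arange(n)  # self where hazard is zero (adds nothing)
    rev_dest[WELL_TKA] = POST_REV1
    rev_dest[t0:t0 + _TUNNEL_MONTHS - 1] = POST_REV2
    rev_dest[R1_LATE] = POST_REV2

    rows = np.arange(n)
    prim_tiers = p.p_rev_primary_by_tier

    def transition(cycle: int, age_years: float) -> np.ndarray:
        qm = lt.monthly_mortality(age_years)
        d = np.full(n, qm)
        d[POST_TKA] = combine_risks(qm, p30p)
        d[POST_REV1] = combine_risks(qm, p30r)
        d[POST_REV2] = combine_risks(qm, p30r)

        r = rev_haz.copy()
        implant_age = cycle - W
        r[WELL_TKA] = (
            revision_monthly_prob(implant_age, prim_tiers) if implant_age >= 1 else 0.0
        )

        step = nxt.copy()
        if cycle == W - 1:
            step[WAIT] = POST_TKA
            step[WAIT_LATE] = POST_TKA
        else:
            step[WAIT] = WAIT if cycle + 1 < relief else WAIT_LATE
            step[WAIT_LATE] = WAIT_LATE

        P = np.zeros((n, n))
        P[rows, DEAD] = d
        np.add.at(P, (rows, step), (1.0 - d) * (1.0 - r))
        np.add.at(P, (rows, rev_dest), (1.0 - d) * r)
        P[DEAD] = 0.0
        P[DEAD, DEAD] = 1.0
        return P

    # per-cycle rewards: annual accrual / 12
    cycle_rewards = np.zeros((n, 2))
    for s in states:
        canon = "WELL_REV1" if s.startswith("WELL_REV1") else s
        cost, util = strategy_rewards(canon, spec)
        cycle_rewards[idx[s]] = (cost / CYCLES_PER_YEAR, util / CYCLES_PER_YEAR)

    one_time = one_time_rewards(spec)
    transition_rewards: dict[tuple[str, str], tuple[float, float]] = {
        ("WELL_TKA", "POST_REV1"): one_time["revision"],
    }
    for s in tunnel + ["WELL_REV1_LATE"]:
        transition_rewards[(s, "POST_REV2")] = one_time["revision"]

    start = np.zeros(n)
    entry_rewards: dict[str, tuple[float, float]] = {}
    if W == 0:
        start[POST_TKA] = 1.0
        entry_rewards["POST_TKA"] = one_time["tka"]
    else:
        start[WAIT if relief > 0 else WAIT_LATE] = 1.0
        transition_rewards[("WAIT", "POST_TKA")] = one_time["tka"]
        transition_rewards[("WAIT_LATE", "POST_TKA")] = one_time["tka"]

    horizon = max(
        1, math.ceil((p.max_age_years - p.cohort_age_years) * CYCLES_PER_YEAR) + CYCLES_PER_YEAR
    )

    return CohortModel(
        states=states,
        death_state="DEAD",
        transition=transition,
        cycle_rewards=cycle_rewards,
        start=start,
        start_age=p.cohort_age_years,
        horizon=horizon,
        transition_rewards=transition_rewards,
        entry_rewards=entry_rewards,
    )


def run_strategy(
    strategy: str,
    params: ParameterSet,
    life_table: LifeTable,
    keep_trace: bool = False,
) -> RunResult:
    """Build and run one strategy; returns its lifetime totals."""
    spec = StrategySpec(strategy, params, life_table)
    result = run(build_strategy(spec), params.discount_annual,
                 half_cycle=params.half_cycle_correction)
    if not keep_trace:
        result = RunResult(
            result.cost, result.qalys, result.cost_undiscounted,
            result.qalys_undiscounted, result.life_years, None,
        )
    return result


def run_all_strategies(
    params: ParameterSet, life_table: LifeTable
) -> dict[str, RunResult]:
    """Run the three strategies under one parameter set."""
    return {s: run_strategy(s, params, life_table) for s in STRATEGIES}
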