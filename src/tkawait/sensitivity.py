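"""Deterministic sensitivity analyses: sweeps, thresholds, wait-time curves.

Every analysis here re-runs the full cohort model at each evaluation point —
nothing is interpolated. Thresholds (parameter values where one strategy
overtakes another on cost or cost-effectiveness) are found by bracketing
bisection on a continuous margin, to $0.01 for dollar-valued parameters and
0.001 for fractions.
"""

from __future__ import annotations

import itertools
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cea import StrategyResult, build_cea_table, net_benefit
from .errors import ConfigurationError, NoCrossingError, ValidationError
from .parameters import CYCLES_PER_YEAR, STRATEGIES, LifeTable, ParameterSet
from .strategies import run_all_strategies, run_strategy

#: default bisection tolerances by parameter kind
TOL_DOLLARS = 0.01
TOL_FRACTION = 0.001

_TIER_NAMES = {
    "p_rev_primary_0_9": ("p_rev_primary_by_tier", 0),
    "p_rev_primary_10_19": ("p_rev_primary_by_tier", 1),
    "p_rev_primary_20plus": ("p_rev_primary_by_tier", 2),
    "p_rev_revision_0_9": ("p_rev_revision_by_tier", 0),
    "p_rev_revision_10_19": ("p_rev_revision_by_tier", 1),
    "p_rev_revision_20plus": ("p_rev_revision_by_tier", 2),
}

_MONTHLY_NAMES = {
    "c_indirect_oa_monthly": "c_indirect_oa_annual",
    "c_bridge_monthly": "c_bridge_annual",
}

_INT_FIELDS = {"wait_months", "bridge_relief_months", "max_age_years"}

_SCALAR_FIELDS = (
    "u_oa", "u_oa_bridge", "u_tka", "u_rev", "dis_rev", "dis_complication",
    "p_early_complication", "p_mort30_primary", "p_mort30_revision",
    "wait_months", "bridge_relief_months", "c_indirect_oa_annual",
    "c_bridge_annual", "c_tka", "c_rev", "indirect_recovery_fraction",
    "bridge_utility_improvement", "discount_annual", "cohort_age_years",
    "max_age_years",
)


def sweepable_names() -> tuple[str, ...]:
    """Parameter names accepted by :func:`with_param` and :func:`sweep`."""
    return _SCALAR_FIELDS + tuple(_TIER_NAMES) + tuple(_MONTHLY_NAMES)


def with_param(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with one named input replaced.

    Accepts plain field names, per-tier revision probabilities
    (``p_rev_primary_0_9`` ...), and monthly-dollar aliases
    (``c_indirect_oa_monthly`` -> annual x 12). Sweeping
    ``bridge_utility_improvement`` switches the bridge utility to the
    gap-fraction formula (clears the explicit bridge utility).
    """
    if name in _TIER_NAMES:
        field, i = _TIER_NAMES[name]
        tiers = list(getattr(params, field))
        tiers[i] = value
        return params.replace(**{field: tuple(tiers)})
    if name in _MONTHLY_NAMES:
        return params.replace(**{_MONTHLY_NAMES[name]: value * CYCLES_PER_YEAR})
    if name == "bridge_utility_improvement":
        return params.replace(bridge_utility_improvement=value, u_oa_bridge=None)
    if name in _SCALAR_FIELDS:
        if name in _INT_FIELDS:
            value = int(round(value))
        return params.replace(**{name: value})
    raise ConfigurationError(f"unknown sweep parameter {name!r}")


# --------------------------------------------------------------------------
# grid sweeps


def sweep(
    axes: Mapping[str, tuple[float, float]],
    n_points: int,
    base: ParameterSet,
    life_table: LifeTable,
    wtp: float = 50_000.0,
) -> pd.DataFrame:
    """Full-model re-run over a 1- to 3-way parameter grid.

    Each axis spans ``[low, high]`` inclusively with ``n_points`` values.
    The result is tidy: one row per grid point with per-strategy cost, QALYs
    and net monetary benefit, plus the preferred strategy.
    """
    if not 1 <= len(axes) <= 3:
        raise ValidationError(f"sweep supports 1-3 axes, got {len(axes)}")
    grids = {}
    for name, (lo, hi) in axes.items():
        if name not in sweepable_names():
            raise ConfigurationError(f"unknown sweep parameter {name!r}")
        if lo == hi and n_points > 1:
            raise ValidationError(f"axis {name!r} has zero width but {n_points} points")
        grids[name] = np.linspace(lo, hi, n_points)

    records = []
    for values in itertools.product(*grids.values()):
        p = base
        for name, value in zip(grids, values):
            p = with_param(p, name, float(value))
        results = run_all_strategies(p, life_table)
        srs = [StrategyResult.from_run(s, r) for s, r in results.items()]
        _, preferred = build_cea_table(srs, wtp)
        row = dict(zip(grids, values))
        for sr in srs:
            nmb, _ = net_benefit(sr, wtp)
            row[f"cost_{sr.strategy}"] = sr.cost
            row[f"qalys_{sr.strategy}"] = sr.qalys
            row[f"nmb_{sr.strategy}"] = nmb
        row["preferred"] = preferred
        records.append(row)
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# threshold (switch-point) finding


def find_crossing(
    objective: Callable[[float], float],
    bracket: tuple[float, float],
    tol: float,
) -> float:
    """Root of a continuous margin by bracketing bisection.

    Raises :class:`NoCrossingError` when the margin has the same sign at both
    bracket ends — the crossing is reported absent, never guessed.
    """
    lo, hi = bracket
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise NoCrossingError(
            f"objective has the same sign at both bracket ends "
            f"({lo}: {f_lo:.4g}, {hi}: {f_hi:.4g})"
        )
    return float(brentq(objective, lo, hi, xtol=tol))


def threshold(
    param: str,
    predicate: Callable[[dict[str, "object"]], float],
    bracket: tuple[float, float],
    tol: float,
    base: ParameterSet,
    life_table: LifeTable,
) -> float:
    """Parameter value at which a strategy-comparison margin flips sign.

    ``predicate`` maps the per-strategy run results (dict of
    :class:`~tkawait.engine.RunResult`) to a signed margin; the model is
    re-run in full at every probe.
    """

    def objective(x: float) -> float:
        p = with_param(base, param, x)
        return float(predicate(run_all_strategies(p, life_table)))

    return find_crossing(objective, bracket, tol)


# -- the named switch-point analyses ---------------------------------------


def indirect_cost_threshold(
    base: ParameterSet, life_table: LifeTable, bracket: tuple[float, float] = (0.0, 857.0)
) -> float:
    """Monthly indirect OA cost above which immediate surgery is cheapest.

    With indirect costs counted, waiting accrues the full indirect cost while
    immediate surgery leaves only the unrecovered residual; the binding
    comparison is against the no-bridge delay (the bridge arm is costlier
    still). Returns $/month.
    """
    p = base.replace(scenario="B")
    return threshold(
        "c_indirect_oa_monthly",
        lambda r: r["immediate_tka"].cost - r["delay_no_bridge"].cost,
        bracket,
        TOL_DOLLARS,
        p,
        life_table,
    )


def bridge_cost_threshold(
    base: ParameterSet, life_table: LifeTable, bracket: tuple[float, float] = (0.0, 1000.0)
) -> float:
    """Monthly bridge cost below which the bridged delay is cheaper than
    immediate surgery (direct costs only). Returns $/month."""
    p = base.replace(scenario="A")
    return threshold(
        "c_bridge_monthly",
        lambda r: r["delay_bridge"].cost - r["immediate_tka"].cost,
        bracket,
        TOL_DOLLARS,
        p,
        life_table,
    )


def indirect_recovery_threshold(
    base: ParameterSet, life_table: LifeTable, bracket: tuple[float, float] = (0.0, 1.0)
) -> float:
    """Fraction of indirect OA costs that surgery must recover for immediate
    surgery to be cheaper than the no-bridge delay (indirect costs counted)."""
    p = base.replace(scenario="B")
    return threshold(
        "indirect_recovery_fraction",
        lambda r: r["delay_no_bridge"].cost - r["immediate_tka"].cost,
        bracket,
        TOL_FRACTION,
        p,
        life_table,
    )


def bridge_relief_threshold(
    base: ParameterSet, life_table: LifeTable, wtp: float = 50_000.0
) -> int:
    """Months of symptomatic relief that make the bridge cost-effective
    against waiting untreated (when immediate surgery is unavailable).

    The bridge is paid for the whole wait but relieves symptoms only for its
    first ``R`` months; returns the smallest whole-month ``R`` whose ICER
    against the untreated wait is at or below ``wtp``.
    """
    wait = int(base.wait_months)

    def icer_at(r_months: int) -> float:
        p = base.replace(bridge_relief_months=r_months, scenario="A")
        res = run_all_strategies(p, life_table)
        d_cost = res["delay_bridge"].cost - res["delay_no_bridge"].cost
        d_qaly = res["delay_bridge"].qalys - res["delay_no_bridge"].qalys
        if d_qaly <= 0:
            return np.inf
        return d_cost / d_qaly

    if icer_at(wait) > wtp:
        raise NoCrossingError(
            f"bridge never cost-effective even with relief for the full "
            f"{wait}-month wait"
        )
    lo, hi = 0, wait  # icer_at(lo) infinite, icer_at(hi) <= wtp
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if icer_at(mid) <= wtp:
            hi = mid
        else:
            lo = mid
    return hi


# --------------------------------------------------------------------------
# wait-time curve


def wait_time_sweep(
    months: Sequence[float],
    base: ParameterSet,
    life_table: LifeTable,
    wtp: float = 50_000.0,
) -> pd.DataFrame:
    """Net-health-benefit curve over surgical wait times.

    Evaluates both delay strategies at each wait (snapped to whole monthly
    cycles) and reports NHB plus incremental cost/QALYs against immediate
    surgery. One row per (wait, strategy).
    """
    snapped = []
    for m in months:
        if m < 0:
            raise ValueError(f"negative wait {m}")
        snapped.append(max(0, int(round(m))))

    immediate = run_strategy("immediate_tka", base, life_table)
    _, nhb_imm = net_benefit(StrategyResult("immediate_tka", immediate.cost, immediate.qalys), wtp)

    records = []
    for m in snapped:
        p = base.replace(wait_months=m)
        for strat in ("delay_bridge", "delay_no_bridge"):
            r = run_strategy(strat, p, life_table)
            _, nhb = net_benefit(StrategyResult(strat, r.cost, r.qalys), wtp)
            records.append(
                {
                    "wait_months": m,
                    "strategy": strat,
                    "cost": r.cost,
                    "qalys": r.qalys,
                    "nhb": nhb,
                    "nhb_immediate": nhb_imm,
                    "d_cost_vs_immediate": r.cost - immediate.cost,
                    "d_qalys_vs_immediate": r.qalys - immediate.qalys,
                }
            )
    return pd.DataFrame.from_records(records)
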