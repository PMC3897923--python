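"""Cost-effectiveness statistics: C/E ratios, ICERs, dominance, net benefit.

Strategies are ranked on the cost-effectiveness frontier: sort by
effectiveness, drop strongly dominated options (costlier and no more
effective than another), flag extendedly dominated ones (their incremental
ratio exceeds that of the next step up the frontier), and prefer the most
effective strategy whose ICER against the adjacent frontier option does not
exceed the willingness-to-pay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .engine import RunResult

STRONGLY_DOMINATED = "strongly dominated"
EXTENDEDLY_DOMINATED = "extendedly dominated"


@dataclass(frozen=True)
class StrategyResult:
    """One strategy's discounted lifetime cost and QALYs."""

    strategy: str
    cost: float
    qalys: float

    def __post_init__(self) -> None:
        if self.qalys < 0:
            raise ValueError(f"{self.strategy}: negative QALYs {self.qalys}")

    @classmethod
    def from_run(cls, strategy: str, result: RunResult) -> "StrategyResult":
        return cls(strategy, result.cost, result.qalys)


def ce_ratio(cost: float, qalys: float) -> float:
    """Average cost-effectiveness ratio, $ per QALY."""
    if qalys <= 0:
        raise ValueError(f"C/E ratio undefined for qalys={qalys}")
    return cost / qalys


def icer(a: StrategyResult, b: StrategyResult) -> float | str:
    """Incremental cost per QALY of ``a`` over ``b``, or a dominance verdict.

    Returns the ratio only when it is informative (one strategy costlier and
    more effective); otherwise a string verdict: ``"a dominates"``,
    ``"b dominates"`` or ``"equivalent"``. Equal effectiveness with unequal
    cost is dominance by the cheaper strategy, never a division by zero.
    """
    if a.strategy == b.strategy:
        raise ValueError("icer() needs two distinct strategies")
    d_cost = a.cost - b.cost
    d_qaly = a.qalys - b.qalys
    if d_cost == 0 and d_qaly == 0:
        return "equivalent"
    if d_cost <= 0 and d_qaly >= 0:
        return "a dominates"
    if d_cost >= 0 and d_qaly <= 0:
        return "b dominates"
    return d_cost / d_qaly


def net_benefit(result: StrategyResult, wtp: float) -> tuple[float, float]:
    """Net monetary and net health benefit at a willingness-to-pay.

    NMB = QALYs*wtp - cost (dollars); NHB = QALYs - cost/wtp (QALYs);
    NMB == NHB*wtp identically.
    """
    if wtp <= 0:
        raise ValueError(f"wtp={wtp} must be > 0")
    nmb = result.qalys * wtp - result.cost
    return nmb, nmb / wtp


def build_cea_table(
    results: Iterable[StrategyResult], wtp: float = 50_000.0
) -> tuple[pd.DataFrame, str]:
    """Rank strategies, compute incrementals, and pick the preferred one.

    Rows are sorted by ascending effectiveness. ICERs are taken against the
    previous non-dominated row. The preferred strategy is the most effective
    non-dominated one whose ICER does not exceed ``wtp`` (a tie at exactly
    ``wtp`` resolves to the more effective strategy). Returns the table and
    the preferred strategy id.
    """
    rows = sorted(results, key=lambda r: (r.qalys, -r.cost))
    names = [r.strategy for r in rows]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate strategy ids in {names}")
    if len(rows) < 2:
        raise ValueError("need at least two strategies to compare")

    dominated: dict[str, str] = {}
    # strong dominance: another strategy is at least as effective and cheaper,
    # or more effective at no extra cost
    for r in rows:
        for other in rows:
            if other is r:
                continue
            if (
                other.cost <= r.cost
                and other.qalys >= r.qalys
                and (other.cost < r.cost or other.qalys > r.qalys)
            ):
                dominated[r.strategy] = STRONGLY_DOMINATED
                break

    # extended dominance: remove frontier members whose incremental ratio
    # exceeds the next segment's, until ICERs increase monotonically
    def frontier() -> list[StrategyResult]:
        return [r for r in rows if r.strategy not in dominated]

    changed = True
    while changed:
        changed = False
        f = frontier()
        for i in range(1, len(f) - 1):
            lo, mid, hi = f[i - 1], f[i], f[i + 1]
            icer_mid = (mid.cost - lo.cost) / (mid.qalys - lo.qalys)
            icer_hi = (hi.cost - mid.cost) / (hi.qalys - mid.qalys)
            if icer_mid > icer_hi:
                dominated[mid.strategy] = EXTENDEDLY_DOMINATED
                changed = True
                break

    f = frontier()
    icers: dict[str, float | None] = {f[0].strategy: None}
    for prev, cur in zip(f, f[1:]):
        icers[cur.strategy] = (cur.cost - prev.cost) / (cur.qalys - prev.qalys)

    preferred = f[0].strategy
    for cur in f[1:]:
        if icers[cur.strategy] <= wtp:
            preferred = cur.strategy

    records = []
    for i, r in enumerate(rows):
        flag = dominated.get(r.strategy)
        nmb, nhb = net_benefit(r, wtp)
        prev = rows[i - 1] if i else None
        records.append(
            {
                "strategy": r.strategy,
                "cost": r.cost,
                "qalys": r.qalys,
                "inc_cost": r.cost - prev.cost if prev else None,
                "inc_qalys": r.qalys - prev.qalys if prev else None,
                "ce_ratio": ce_ratio(r.cost, r.qalys),
                "icer": None if flag else icers.get(r.strategy),
                "dominance": flag,
                "nmb": nmb,
                "nhb": nhb,
            }
        )
    table = pd.DataFrame.from_records(records)
    return table, preferred


def format_cea_table(table: pd.DataFrame) -> pd.DataFrame:
    """Round dollar ratios to whole dollars for display (internal math is
    full precision)."""
    out = table.copy()
    for col in ("cost", "inc_cost", "ce_ratio", "icer", "nmb"):
        out[col] = pd.to_numeric(out[col], errors="coerce").round(0)
    out["qalys"] = out["qalys"].round(2)
    for col in ("inc_qalys", "nhb"):
        out[col] = pd.to_numeric(out[col], errors="coerce").round(4)
    return out
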