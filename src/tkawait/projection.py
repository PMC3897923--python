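"""Population-level cost of waiting, given annual procedure volumes.

Scales the per-patient incremental cost and QALY loss of a delay strategy
(versus immediate surgery) by user-supplied projected annual primary-TKA
volumes. Each calendar year's cohort is valued at its own start — totals are
not discounted across calendar years.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError
from .parameters import LifeTable, ParameterSet
from .strategies import run_strategy

logger = logging.getLogger(__name__)


def read_volumes(path: str | Path) -> pd.DataFrame:
    """Read a ``year,volume`` CSV of projected annual primary-TKA counts."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["year", "volume"]:
        raise FormatError(f"{path}: expected header 'year,volume', got {list(df.columns)}")
    if df.empty:
        raise ValidationError(f"{path}: volume table is empty")
    if df["year"].duplicated().any():
        dups = df.loc[df["year"].duplicated(), "year"].tolist()
        raise ValidationError(f"{path}: duplicate years {dups}")
    if (df["volume"] < 0).any():
        raise ValidationError(f"{path}: negative volumes")
    logger.info("read volume table %s: %d rows", path, len(df))
    return df.sort_values("year").reset_index(drop=True)


def per_patient_incremental(
    wait_months: int,
    strategy: str,
    scenario: str,
    base: ParameterSet,
    life_table: LifeTable,
) -> tuple[float, float]:
    """(delta cost $, delta QALYs) of one delayed patient vs immediate surgery.

    Both arms are run in full under the given cost scenario; the delta is
    delayed minus immediate (so waiting shows a positive cost and negative
    QALY increment under the base case).
    """
    if not 0 <= wait_months <= 60:
        raise ValueError(f"wait_months={wait_months} outside [0, 60]")
    p = base.replace(wait_months=int(wait_months), scenario=scenario)
    delayed = run_strategy(strategy, p, life_table)
    immediate = run_strategy("immediate_tka", p, life_table)
    return delayed.cost - immediate.cost, delayed.qalys - immediate.qalys


def population_projection(
    volumes: pd.DataFrame,
    wait_months: int,
    strategy: str,
    scenario: str,
    base: ParameterSet,
    life_table: LifeTable,
) -> pd.DataFrame:
    """Per-year incremental societal cost and QALY loss of delaying surgery.

    ``volumes`` must have columns ``year`` and ``volume``; each year's totals
    are its volume times the per-patient increments.
    """
    if volumes.empty:
        raise ValidationError("volume table is empty")
    d_cost, d_qalys = per_patient_incremental(
        wait_months, strategy, scenario, base, life_table
    )
    out = volumes[["year", "volume"]].copy()
    out["inc_cost"] = out["volume"] * d_cost
    out["inc_qalys"] = out["volume"] * d_qalys
    return out
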