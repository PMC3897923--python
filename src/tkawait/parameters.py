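"""Model parameters, life tables, and the small time-conversion primitives.

All clinical and economic inputs of the knee-arthroplasty decision model live
in :class:`ParameterSet`; background mortality lives in :class:`LifeTable`.
Annual quantities (utilities, costs, probabilities, the discount rate) are
converted to the model's one-month cycle with the standard constant-hazard
and compound-discount formulas exposed here.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

CYCLES_PER_YEAR = 12

#: Strategy identifiers used everywhere (CLI flags, output tables, results).
STRATEGIES = ("immediate_tka", "delay_bridge", "delay_no_bridge")


# --------------------------------------------------------------------------
# time conversions


def annual_to_monthly_prob(p_annual: float) -> float:
    """Convert an annual event probability to a monthly one.

    Uses the constant-hazard relation ``1 - (1 - p)**(1/12)``, so that twelve
    independent monthly draws recover the annual probability exactly.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"annual probability {p_annual!r} outside [0, 1]")
    return 1.0 - (1.0 - p_annual) ** (1.0 / CYCLES_PER_YEAR)


def monthly_discount_factor(annual_rate: float) -> float:
    """Per-cycle discount factor ``(1 + r)**(-1/12)``.

    Twelve cycles compound to exactly one annual discount step ``1/(1 + r)``.
    """
    if annual_rate < 0.0:
        raise ValueError(f"discount rate {annual_rate!r} must be >= 0")
    return (1.0 + annual_rate) ** (-1.0 / CYCLES_PER_YEAR)


# --------------------------------------------------------------------------
# parameter set


@dataclass(frozen=True)
class ParameterSet:
    """Every input of the decision model, in annual units and dollars.

    Utilities are annual quality weights in [0, 1]; disutilities are one-time
    QALY deductions in [-1, 0]; probabilities are annual unless named
    otherwise; costs are dollars. ``scenario`` selects the costing
    perspective: ``"A"`` counts direct medical costs only, ``"B"`` adds the
    indirect (productivity/caregiver) costs of end-stage knee OA.
    """

    # health-state utilities (QALY / year)
    u_oa: float = 0.6
    u_oa_bridge: float | None = 0.7
    u_tka: float = 0.9
    u_rev: float = 0.85

    # one-time disutilities (QALY)
    dis_rev: float = -0.1
    dis_complication: float = -0.20

    # transition probabilities (annual unless stated)
    p_early_complication: float = 0.01
    p_rev_primary_by_tier: tuple[float, float, float] = (0.005, 0.01, 0.02)
    p_rev_revision_by_tier: tuple[float, float, float] = (0.01, 0.02, 0.04)
    p_mort30_primary: float = 0.007
    p_mort30_revision: float = 0.01

    # timing
    wait_months: int = 24
    bridge_relief_months: int | None = None  # None: relief spans the whole wait

    # costs ($)
    c_indirect_oa_annual: float = 10_369.0
    c_bridge_annual: float = 2_500.0
    c_tka: float = 26_865.0
    c_rev: float = 35_542.0
    indirect_recovery_fraction: float = 0.80
    bridge_utility_improvement: float = 0.33

    # run settings
    discount_annual: float = 0.03
    cohort_age_years: float = 60.0
    scenario: str = "A"
    max_age_years: int = 110
    include_complications: bool = True
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_rev_primary_by_tier", tuple(self.p_rev_primary_by_tier))
        object.__setattr__(self, "p_rev_revision_by_tier", tuple(self.p_rev_revision_by_tier))
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        def _bound(name: str, value: float, lo: float, hi: float) -> None:
            if not lo <= value <= hi:
                raise ValidationError(f"{name}={value!r} outside [{lo}, {hi}]")

        for name in ("u_oa", "u_tka", "u_rev"):
            _bound(name, getattr(self, name), 0.0, 1.0)
        if self.u_oa_bridge is not None:
            _bound("u_oa_bridge", self.u_oa_bridge, 0.0, 1.0)
        for name in ("dis_rev", "dis_complication"):
            _bound(name, getattr(self, name), -1.0, 0.0)
        for name in ("p_early_complication", "p_mort30_primary", "p_mort30_revision"):
            _bound(name, getattr(self, name), 0.0, 1.0)
        for name in ("p_rev_primary_by_tier", "p_rev_revision_by_tier"):
            tiers = getattr(self, name)
            if len(tiers) != 3:
                raise ValidationError(f"{name} must have 3 tiers, got {len(tiers)}")
            for i, p in enumerate(tiers):
                _bound(f"{name}[{i}]", p, 0.0, 1.0)
            # base-case tiers rise with implant age, but sensitivity ranges
            # legitimately explore non-monotone combinations — warn only
            if not (tiers[0] <= tiers[1] <= tiers[2]):
                logger.warning("%s=%s not non-decreasing across implant-age tiers",
                               name, tiers)
        if self.wait_months < 0:
            raise ValidationError(f"wait_months={self.wait_months} must be >= 0")
        if self.bridge_relief_months is not None and self.bridge_relief_months < 0:
            raise ValidationError("bridge_relief_months must be >= 0")
        for name in ("c_indirect_oa_annual", "c_bridge_annual", "c_tka", "c_rev"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        _bound("indirect_recovery_fraction", self.indirect_recovery_fraction, 0.0, 1.0)
        _bound("bridge_utility_improvement", self.bridge_utility_improvement, 0.0, 1.0)
        if self.discount_annual < 0:
            raise ValidationError("discount_annual must be >= 0")
        if self.scenario not in ("A", "B"):
            raise ValidationError(f"scenario must be 'A' or 'B', got {self.scenario!r}")
        if self.max_age_years < self.cohort_age_years:
            raise ValidationError("max_age_years must be >= cohort_age_years")

    # -- derived quantities --------------------------------------------------

    @property
    def bridge_wait_utility(self) -> float:
        """Annual utility during the wait under the non-operative bridge.

        The explicit bridge utility (0.7 in the base case) takes precedence;
        when it is unset the bridge is assumed to close a fixed fraction of
        the OA-to-TKA utility gap (33% in the base case).
        """
        if self.u_oa_bridge is not None:
            return self.u_oa_bridge
        return self.u_oa + self.bridge_utility_improvement * (self.u_tka - self.u_oa)

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["p_rev_primary_by_tier"] = list(self.p_rev_primary_by_tier)
        d["p_rev_revision_by_tier"] = list(self.p_rev_revision_by_tier)
        return d


#: Config keys that must appear in a parameter file (the clinical/economic
#: inputs); run settings fall back to base-case defaults when omitted.
REQUIRED_KEYS = (
    "u_oa",
    "u_oa_bridge",
    "u_tka",
    "u_rev",
    "dis_rev",
    "dis_complication",
    "p_early_complication",
    "p_rev_primary_by_tier",
    "p_rev_revision_by_tier",
    "p_mort30_primary",
    "p_mort30_revision",
    "wait_months",
    "c_indirect_oa_annual",
    "c_bridge_annual",
    "c_tka",
    "c_rev",
)

_OPTIONAL_KEYS = tuple(
    f.name for f in dataclasses.fields(ParameterSet) if f.name not in REQUIRED_KEYS
)


@dataclass(frozen=True)
class SensitivityRange:
    """One-way sensitivity range for a named parameter."""

    parameter: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValidationError(
                f"range for {self.parameter!r}: low {self.low} > high {self.high}"
            )


def load_parameters(path: str | Path) -> tuple[ParameterSet, dict[str, SensitivityRange]]:
    """Load and validate a YAML parameter file.

    Returns the validated :class:`ParameterSet` together with any sensitivity
    ranges declared under the ``sensitivity:`` key (``name: [low, high]``).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"parameter file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping of parameter names")
    missing = [k for k in REQUIRED_KEYS if k not in raw]
    if missing:
        raise ConfigurationError(f"{path}: missing required keys: {', '.join(missing)}")
    sens_raw = raw.get("sensitivity", {}) or {}
    known = set(REQUIRED_KEYS) | set(_OPTIONAL_KEYS)
    unknown = [k for k in raw if k not in known and k != "sensitivity"]
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys: {', '.join(sorted(unknown))}")
    kwargs = {k: v for k, v in raw.items() if k != "sensitivity"}
    params = ParameterSet(**kwargs)
    ranges = {
        name: SensitivityRange(name, float(lo), float(hi))
        for name, (lo, hi) in sens_raw.items()
    }
    logger.info("loaded %d parameters (+%d ranges) from %s", len(kwargs), len(ranges), path)
    return params, ranges


def save_parameters(params: ParameterSet, path: str | Path,
                    ranges: Mapping[str, SensitivityRange] | None = None) -> None:
    """Write a parameter file that :func:`load_parameters` reads back exactly."""
    doc = params.to_dict()
    if ranges:
        doc["sensitivity"] = {r.parameter: [r.low, r.high] for r in ranges.values()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def base_case() -> ParameterSet:
    """The base-case parameter set (all defaults)."""
    return ParameterSet()


def bundled_config_path() -> Path:
    """Path to the bundled base-case parameter file."""
    return Path(str(resources.files("tkawait.data") / "base_case.yaml"))


# --------------------------------------------------------------------------
# life tables


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual all-cause death probabilities.

    Ages must be contiguous integers; the final age is treated as the end of
    the table — any lookup beyond it returns certain death within the year.
    """

    ages: np.ndarray  # (n,) int
    qx: np.ndarray  # (n,) float, annual death probability

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise FormatError("life table must be two equal-length 1-D columns")
        if not np.all(np.diff(ages) == 1):
            raise FormatError("life table ages must be contiguous integers")
        if np.any((qx < 0) | (qx > 1)):
            bad = ages[(qx < 0) | (qx > 1)]
            raise ValidationError(f"life table q outside [0, 1] at ages {bad.tolist()}")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q_annual(self, age_years: float) -> float:
        """Annual death probability at the integer age containing ``age_years``."""
        age = int(np.floor(age_years))
        if age < self.min_age:
            raise ValueError(f"age {age_years} below life-table minimum {self.min_age}")
        if age > self.max_age:
            return 1.0
        return float(self.qx[age - self.min_age])

    def monthly_mortality(self, age_years: float) -> float:
        """Monthly death probability at ``age_years`` (constant within each year)."""
        q = self.q_annual(age_years)
        if q >= 1.0:
            return 1.0
        return annual_to_monthly_prob(q)

    def life_expectancy(self, age_years: int) -> float:
        """Curtate expectation of life plus a half-year correction."""
        q = self.qx[int(age_years) - self.min_age:]
        surv = np.cumprod(1.0 - q)
        return float(surv.sum()) + 0.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


def monthly_mortality(lt: LifeTable, age_years: float) -> float:
    """Module-level alias for :meth:`LifeTable.monthly_mortality`."""
    return lt.monthly_mortality(age_years)


def read_life_table(path: str | Path) -> LifeTable:
    """Read a ``age,qx`` CSV into a validated :class:`LifeTable`."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["age", "qx"]:
        raise FormatError(f"{path}: expected header 'age,qx', got {list(df.columns)}")
    df = df.sort_values("age")
    ages = df["age"].to_numpy()
    if not np.all(ages == np.round(ages)):
        raise FormatError(f"{path}: ages must be integers")
    lt = LifeTable(ages.astype(int), df["qx"].to_numpy(float))
    logger.info("read life table %s: %d rows, ages %d-%d", path, len(df), lt.min_age, lt.max_age)
    return lt


def write_life_table(lt: LifeTable, path: str | Path) -> None:
    lt.to_frame().to_csv(path, index=False)


def bundled_life_table() -> LifeTable:
    """The bundled synthetic US-2009-style all-sex life table (ages 0-110)."""
    return read_life_table(str(resources.files("tkawait.data") / "life_table_us2009_synthetic.csv"))
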