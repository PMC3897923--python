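"""Synthetic inputs: parametric life tables, parameter draws, toy fixtures.

The decision model needs an age-specific background-mortality table. Rather
than depending on any particular national publication, this module generates
Gompertz life tables — an exponential-in-age hazard that reproduces adult
mortality schedules well — and the bundled fixture is one such table
calibrated to US-2009 all-sex demographics (life expectancy ~22.5 y at age
60, ~79 y at birth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .parameters import LifeTable, ParameterSet, SensitivityRange

#: Gompertz calibration of the bundled US-2009-style table: hazard
#: a*exp(b*age) with e(60) ~= 22.5 y, q(60) ~= 0.0093, q(80) ~= 0.055.
US2009_STYLE = None  # set below, after GompertzSpec is defined


@dataclass(frozen=True)
class GompertzSpec:
    """Gompertz hazard ``h(age) = a * exp(b * age)`` truncated at ``max_age``."""

    a: float
    b: float
    max_age: int = 110

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValidationError(f"Gompertz a={self.a} must be > 0")
        if self.b < 0:
            raise ValidationError(f"Gompertz b={self.b} must be >= 0")
        if self.max_age < 1:
            raise ValidationError(f"max_age={self.max_age} must be >= 1")


US2009_STYLE = GompertzSpec(a=4.2e-5, b=0.09, max_age=110)


def gompertz_life_table(spec: GompertzSpec = US2009_STYLE) -> LifeTable:
    """Annual death probabilities ``q(age) = 1 - exp(-a * e**(b*age))``.

    The hazard is integrated over one year as if constant at its start-of-year
    value; the final age is forced to q=1 so the table closes out.
    """
    ages = np.arange(0, spec.max_age + 1)
    q = 1.0 - np.exp(-spec.a * np.exp(spec.b * ages))
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0
    return LifeTable(ages, q)


def sample_parameter_sets(
    base: ParameterSet,
    ranges: dict[str, SensitivityRange],
    n: int,
    seed: int,
) -> list[ParameterSet]:
    """Draw ``n`` parameter sets uniformly over the given sensitivity ranges.

    Parameters not named in ``ranges`` stay at their base value. Deterministic
    given ``seed``. The deterministic cohort pipeline itself uses no
    randomness; these draws exist for robustness checks over the ranges.
    """
    from .sensitivity import with_param, sweepable_names  # local: avoid cycle

    if n < 1:
        raise ValueError(f"n={n} must be >= 1")
    valid = sweepable_names()
    for name in ranges:
        if name not in valid:
            raise ConfigurationError(f"unknown sweep parameter {name!r}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        p = base
        for name, r in ranges.items():
            p = with_param(p, name, float(rng.uniform(r.low, r.high)))
        out.append(p)
    return out


def toy_fixture() -> tuple[ParameterSet, LifeTable]:
    """A miniature configuration with closed-form lifetime totals.

    Constant annual mortality q=0.12 at every age, zero discounting, no
    revisions, no complications, no perioperative mortality, zero costs.
    With monthly survival ``s = 0.88**(1/12)``, the immediate-surgery arm's
    undiscounted QALY total has the geometric closed form
    ``(u_tka/12) / (1 - s)``, which engine tests check to 1e-9.
    """
    params = ParameterSet(
        p_early_complication=0.0,
        p_rev_primary_by_tier=(0.0, 0.0, 0.0),
        p_rev_revision_by_tier=(0.0, 0.0, 0.0),
        p_mort30_primary=0.0,
        p_mort30_revision=0.0,
        dis_rev=0.0,
        dis_complication=0.0,
        c_indirect_oa_annual=0.0,
        c_bridge_annual=0.0,
        c_tka=0.0,
        c_rev=0.0,
        discount_annual=0.0,
        cohort_age_years=60.0,
        max_age_years=1000,  # effectively no age cap: absorption ends the run
        include_complications=False,
    )
    ages = np.arange(0, 1001)
    q = np.full(ages.shape, 0.12)
    q[-1] = 1.0
    lt = LifeTable(ages, q)
    return params, lt
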