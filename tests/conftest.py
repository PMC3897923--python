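import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tkawait import base_case, bundled_life_table, toy_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return base_case()


@pytest.fixture(scope="session")
def life_table():
    return bundled_life_table()


@pytest.fixture(scope="session")
def toy():
    return toy_fixture()


@pytest.fixture(scope="session")
def base_runs(params, life_table):
    """Base-case runs for both cost scenarios, computed once per session."""
    from tkawait import run_all_strategies

    return {
        scen: run_all_strategies(params.replace(scenario=scen), life_table)
        for scen in ("A", "B")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
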