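import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ascot_bws.design import build_design
from ascot_bws.instrument import (
    AttributeLevel,
    Domain,
    InstrumentSpec,
    default_instrument,
)
from ascot_bws.reference import austria_reference_params
from ascot_bws.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def spec():
    return default_instrument()


@pytest.fixture(scope="session")
def plan():
    return build_design(seed=0)


@pytest.fixture(scope="session")
def reference_params():
    return austria_reference_params()


@pytest.fixture(scope="session")
def small_dataset(plan):
    """12 simulated respondents at the published generating values."""
    return simulate_dataset(SimulationConfig(n_respondents=12, seed=7), plan)


def toy_instrument(n_domains: int) -> InstrumentSpec:
    """A reduced instrument with generic statements, for small exact checks."""
    domains = tuple(
        Domain(
            f"D{i}",
            f"Domain {i}",
            tuple(f"Domain {i} statement level {l}" for l in range(1, 5)),
        )
        for i in range(n_domains)
    )
    return InstrumentSpec(
        domains=domains, reference_item=AttributeLevel("D0", 4), joint_pair=None
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_16)
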