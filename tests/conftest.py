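import numpy as np
import pytest

from gemtailor import tailor_all
from gemtailor.synthetic_data import generate_scenario, generate_toy_gem


@pytest.fixture()
def toy1():
    """The four-reaction parallel-pathway toy (EX_A, R1, R2, BIO)."""
    return generate_toy_gem(0, "minimal")


@pytest.fixture(scope="session")
def scenario():
    """Standard synthetic drought scenario at the suite's frozen seed."""
    return generate_scenario(1)


@pytest.fixture(scope="session")
def tailored(scenario):
    """Full threshold sweep on the scenario (shared: it is the slow step)."""
    series = scenario.expression.series()
    gems, report = tailor_all(
        scenario.gem, series, scenario.growth, list(scenario.config.q_grid)
    )
    return gems, report


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260905)
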