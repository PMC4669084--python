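import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sipriming.mineralisation import default_design
from sipriming.simulate import paper_scenario, simulate_experiment

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def rates_sim():
    """Noise-free simulation with the printed interval rates as truth."""
    return simulate_experiment(paper_scenario("rates-paper"), seed=1)


@pytest.fixture(scope="session")
def cumulative_sim():
    """Noise-free simulation with the printed cumulative fractions as truth."""
    return simulate_experiment(paper_scenario("cumulative-paper"), seed=1)


@pytest.fixture()
def toy_oneway():
    """Two groups {1,2,3} vs {4,5,6}: SSB=13.5, MSW=1.0, F=13.5 on (1,4) df."""
    return pd.DataFrame(
        {"y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "g": ["a"] * 3 + ["b"] * 3}
    )
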