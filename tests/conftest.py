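import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from agriair.synth import SynthConfig, generate_panel

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale configuration shared across test modules."""
    return SynthConfig(n_counties=80, n_years=8, seed=3)


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, truth = generate_panel(small_config)
    return panel, truth


@pytest.fixture(scope="session")
def tiny_config():
    return SynthConfig(n_counties=30, n_years=6, seed=12)


@pytest.fixture(scope="session")
def tiny_panel(tiny_config):
    panel, truth = generate_panel(tiny_config)
    return panel, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
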