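import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_screen():
    """A modest simulated backcross screen shared across scoring tests."""
    from photoscreen.simulate import TruthConfig, simulate_backcross_screen

    cfg = TruthConfig(n_mutants=300, depth=500_000, seed=42)
    library, counts, truth = simulate_backcross_screen(cfg)
    return cfg, library, counts, truth


@pytest.fixture(scope="session")
def chloro_annotation():
    from photoscreen.simulate import default_annotation

    return default_annotation()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
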