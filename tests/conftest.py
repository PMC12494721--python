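import numpy as np
import pandas as pd
import pytest

from aminescreen.pipeline import run_screen
from aminescreen.simulate import SimulationScenario, generate_screen

SMALL_SPECIES = {
    "Escherichia coli": ("putrescine", "cadaverine"),
    "Ruminococcus gnavus": ("tryptamine",),
}


@pytest.fixture(scope="session")
def small_scenario():
    return SimulationScenario(
        n_compounds=150,
        species_metabolites=dict(SMALL_SPECIES),
        fraction_hits=0.08,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_screen(small_scenario):
    """A small simulated screen: (measurements, growth, library, truth)."""
    return generate_screen(small_scenario)


@pytest.fixture(scope="session")
def small_result(small_screen):
    measurements, growth, library, truth = small_screen
    return run_screen(measurements, growth)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
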