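import numpy as np
import pandas as pd
import pytest

from puma_energetics.annotate import annotate_fixes
from puma_energetics.config import StudyConfig
from puma_energetics.simulate import LandscapeSpec, SimScenario, simulate_dataset


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def small_dataset(config):
    """Two animals x three days: enough for every pipeline stage, fast."""
    scenario = SimScenario(n_males=1, n_females=1, n_days=3)
    fixes, houses, habitat, truths = simulate_dataset(scenario, seed=7, config=config)
    return scenario, fixes, houses, habitat, truths


@pytest.fixture(scope="session")
def small_annotated(small_dataset, config):
    scenario, fixes, houses, habitat, truths = small_dataset
    return annotate_fixes(fixes, houses, habitat, config)


@pytest.fixture()
def tiny_fixes() -> pd.DataFrame:
    """Three hand-written fixes for one animal at the nominal cadence."""
    return pd.DataFrame(
        {
            "animal_id": ["p1", "p1", "p1"],
            "timestamp": pd.to_datetime(
                ["2011-01-03T12:00:00Z", "2011-01-03T12:15:00Z", "2011-01-03T12:30:00Z"]
            ),
            "x": [0.0, 30.0, 130.0],
            "y": [0.0, 40.0, 40.0],
        }
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20110103)
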