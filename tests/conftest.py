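import numpy as np
import pandas as pd
import pytest

from protmed.simulate import SimulationConfig, simulate_trial


@pytest.fixture(scope="session")
def small_trial():
    """A compact simulated trial: 200 subjects, 12 proteins, 3 mediators."""
    cfg = SimulationConfig(
        n_subjects=200,
        n_proteins=12,
        mediators={"P001": (0.5, -0.05), "P002": (0.4, -0.04), "P003": (-0.35, 0.05)},
        direct_effect=-0.05,
        seed=11,
    )
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_trial):
    return small_trial[0]


@pytest.fixture
def tiny_csv(tmp_path):
    """A 3-subject wide table covering all three visits."""
    df = pd.DataFrame({
        "subject_id": ["a", "b", "c"],
        "arm": [1, 0, 1],
        "picp__baseline": [80.0, 95.5, 70.25],
        "picp__v1": [75.0, 96.0, 71.0],
        "picp__v2": [72.0, 97.0, 69.5],
        "P001__baseline": [5.0, 6.0, 4.5],
        "P001__v1": [5.5, 6.0, 4.0],
        "P001__v2": [6.0, 5.5, 4.25],
    })
    path = tmp_path / "trial.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
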