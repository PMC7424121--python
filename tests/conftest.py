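import numpy as np
import pandas as pd
import pytest

from morphcp import SimulationConfig, simulate
from morphcp.data_model import TRIAL_COLUMNS


@pytest.fixture(scope="session")
def exp1_sim():
    """One default blocked-design simulation (shared, read-only)."""
    trials, continua, truth = simulate(SimulationConfig(design="exp1", seed=7))
    return trials, continua, truth


@pytest.fixture(scope="session")
def exp2_sim():
    trials, continua, truth = simulate(SimulationConfig(design="exp2", seed=7))
    return trials, continua, truth


@pytest.fixture
def small_trials():
    """Four hand-written valid trials on one continuum."""
    return pd.DataFrame(
        {
            "participant_id": ["P01", "P01", "P02", "P02"],
            "continuum_id": ["uf1"] * 4,
            "condition": ["unfamiliar_familiar"] * 4,
            "morph_pct": [10, 50, 60, 90],
            "response": ["A", "B", "B", "B"],
            "rt_ms": [432.0, 800.5, 1200.0, 300.0],
            "block": [0, 0, 1, 1],
        },
        columns=list(TRIAL_COLUMNS),
    )


def bernoulli_trials(p, n_participants, n_per, seed, condition="stranger_friend", morph=50):
    """Single-level Bernoulli(p) responses, one continuum, for CI studies."""
    rng = np.random.default_rng(seed)
    resp = rng.random(n_participants * n_per) < p
    return pd.DataFrame(
        {
            "participant_id": np.repeat(
                [f"P{i:02d}" for i in range(n_participants)], n_per
            ),
            "continuum_id": "c1",
            "condition": condition,
            "morph_pct": morph,
            "response": np.where(resp, "B", "A"),
            "rt_ms": 700.0,
            "block": 0,
        }
    )
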