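import numpy as np
import pandas as pd
import pytest

from driftgaze.fitting import FitOptions
from driftgaze.params import DDMParams
from driftgaze.synth import SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_params():
    """The shared generating truth of the face/preview condition."""
    return DDMParams(a=1.0, zr=0.5, v=0.607, t0=0.208, sv=0.3, sz=0.1, st0=0.08)


@pytest.fixture(scope="session")
def small_session():
    """Two participants, 64 trials per condition, simulated once per run."""
    cfg = SyntheticConfig(
        n_participants=2, trials_per_condition=64, n_stimuli_per_category=64, seed=7
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def fast_fit_options():
    """Cheap but convergent fitting options for unit tests."""
    return FitOptions(
        restarts=1, rounds=2, seed=3, maxfev_per_dim=30, n_grid=128, n_sz=5, n_st0=5
    )


def make_trials(records) -> pd.DataFrame:
    """Small literal trial tables for hand-computed fixtures."""
    return pd.DataFrame(
        records,
        columns=["participant_id", "inspection_identity", "preview", "choice",
                 "fixation_duration_ms"],
    )
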