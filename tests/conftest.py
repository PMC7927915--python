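import numpy as np
import pytest

from replayburst.io import RecordingSession
from replayburst.synthetic import (
    SimConfig,
    StateComponent,
    gen_localizer,
    gen_state_path,
    gen_state_signals,
)

TASK_PAIRS = [(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (6, 7)]


@pytest.fixture(scope="session")
def small_localizer():
    """Coarse-grid localizer whose envelope peaks exactly at 200 ms."""
    loc, patterns = gen_localizer(
        S=8, n_trials=160, P=12, fs=50.0, peri_ms=400.0, peak_ms=200.0,
        snr=1.5, seed=0, envelope_sd_ms=20.0,
    )
    return loc, patterns


@pytest.fixture(scope="session")
def two_state_session():
    """Slow-switching 2-state recording: 5 Hz vs 25 Hz coherent pairs."""
    T = 25000
    trans = np.array([[0.999, 0.001], [0.001, 0.999]])
    path = gen_state_path(2, trans, T, 0)
    spec = {
        0: [StateComponent(5.0, (0, 1), 2.0, True)],
        1: [StateComponent(25.0, (2, 3), 2.0, True)],
    }
    session = gen_state_signals(path, 250.0, spec, 0.5, 1, n_channels=4)
    return session, path


@pytest.fixture(scope="session")
def white_session():
    rng = np.random.default_rng(11)
    return RecordingSession(rng.standard_normal((3, 20000)), 250.0)


@pytest.fixture(scope="session")
def micro_sim_config():
    """Tiny full-fixture config for integration tests."""
    return SimConfig(
        n_subjects=3, duration_s=40.0, fs=250.0, fs_hi=600.0,
        n_channels=6, K=3, state_freqs=(4.0, 10.0, 25.0),
        n_stimuli=8, n_trials=80,
    )
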