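import numpy as np
import pytest

from obci.synth import (
    SessionConfig,
    generate_trials,
    simulate_session,
)


@pytest.fixture(scope="session")
def small_config():
    return SessionConfig(
        fov_height_px=48, fov_width_px=48, n_trials_per_target=14, rng_seed=3
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    """One small rendered session shared across tests (read-only)."""
    return simulate_session(small_config)


@pytest.fixture(scope="session")
def default_behavior():
    """Default-scale behavior (40 trials/target) without a rendered movie."""
    cfg = SessionConfig(n_trials_per_target=40, rng_seed=11)
    trials, hand = generate_trials(cfg, cfg.rng())
    frame_times = np.arange(
        0.0, trials["trial_end_ms"].max() + 400.0, 1000.0 / cfg.frame_rate
    )
    return cfg, trials, hand, frame_times
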