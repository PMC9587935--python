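import warnings

import numpy as np
import pytest

from soundloc3d.simulate import DEFAULT_RESPONSE_BIAS, GeneratorConfig, generate_experiment

# the 50 Hz default cutoff sits at Nyquist for 100 Hz tracks and is clamped
# with a RuntimeWarning by design; keep test output clean
warnings.filterwarnings("ignore", message="cutoff .* clamping", category=RuntimeWarning)

ZERO = {"azimuth": 0.0, "elevation": 0.0, "depth": 0.0}


def zero_noise_config(**overrides) -> GeneratorConfig:
    """A generator config whose responses equal their targets exactly."""
    base = dict(
        n_participants=3,
        trials_per_cell=2,
        placement_noise_sd_cm=0.0,
        response_bias={k: dict(ZERO) for k in DEFAULT_RESPONSE_BIAS},
        response_sd={k: dict(ZERO) for k in DEFAULT_RESPONSE_BIAS},
        participant_bias_sd=dict(ZERO),
        depth_gain=1.0,
        depth_intercept_cm=0.0,
        anticipatory_rate=0.0,
        head_move_in_static_rate=0.0,
        head_jitter_amp_m=0.0,
        seed=11,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_experiment():
    """4 participants x 2 trials/cell with full tracks (default stated world)."""
    return generate_experiment(GeneratorConfig(n_participants=4, trials_per_cell=2, seed=7))


@pytest.fixture(scope="session")
def labeled_violation_experiment():
    """Noiseless tracks with elevated violation rates and exact ground truth."""
    cfg = zero_noise_config(
        n_participants=2,
        anticipatory_rate=0.2,
        head_move_in_static_rate=0.15,
        seed=23,
    )
    return generate_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
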