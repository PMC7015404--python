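import numpy as np
import pytest

import synkit as sk
from synkit.preprocessing import ensure_scaled


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gt3():
    """A fixed 3-synergy ground truth on 8 muscles."""
    return sk.make_ground_truth(8, 3, seed=7)


@pytest.fixture
def clean_env3(gt3):
    """Noiseless envelope matrix from the 3-synergy ground truth."""
    cfg = sk.SimulationConfig(envelope_noise_sd=0.0, seed=7)
    return sk.simulate_envelope(gt3, cfg)


@pytest.fixture
def scaled_env3(clean_env3):
    return ensure_scaled(clean_env3)


def make_scaled_envelope(n_syn, seed, noise=0.0, **cfg_kwargs):
    """Seeded scaled envelope + its ground truth (shared test helper)."""
    gt = sk.make_ground_truth(8, n_syn, seed=seed)
    cfg = sk.SimulationConfig(envelope_noise_sd=noise, seed=seed, **cfg_kwargs)
    return gt, ensure_scaled(sk.simulate_envelope(gt, cfg))
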