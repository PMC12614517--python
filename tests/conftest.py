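import numpy as np
import pytest

from ambientgait import (
    JointStream,
    VibeParams,
    WalkerParams,
    simulate_trial,
)


@pytest.fixture(scope="session")
def nominal_trial():
    """One bimodal trial at nominal noise (shared across tests; 4 kHz keeps
    the floor half light)."""
    return simulate_trial(WalkerParams(),
                          VibeParams(sample_rate=4096.0, daq_lag=0.25),
                          seed=7)


@pytest.fixture(scope="session")
def clean_floor_trial():
    """Noise-free, jitter-free floor trial for exactness checks."""
    walker = WalkerParams(joint_noise_sd=0.0, dropout_prob=0.0,
                          timestamp_jitter_sd=0.0)
    # a whisper of sensor noise keeps the median-normalized SNR statistic
    # well defined (an exactly silent floor has zero median power)
    vibe = VibeParams(sample_rate=4096.0, noise_sd=1e-3, amp_jitter=0.0)
    return simulate_trial(walker, vibe, seed=3)


def rigid_transform(stream: JointStream, rng: np.random.Generator) -> JointStream:
    """Apply one random rotation + translation to every joint of a stream."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(0.0, 5.0, 3)
    pos = stream.positions @ R.T + t
    return JointStream(stream.timestamps.copy(), pos, stream.joint_names)
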