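import numpy as np
import pytest

from alphadrift.epochs import EpochSet
from alphadrift.synthgen import CohortConfig, SourceSpec, generate_subject


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_sine_epochs(
    freq_hz=10.0,
    n_channels=2,
    n_trials=4,
    fs=250.0,
    span=(-1.0, 1.0),
    amplitude=1.0,
    phase=0.0,
):
    """Noise-free constant-frequency sinusoid epochs (same signal every channel)."""
    n = int(round((span[1] - span[0]) * fs))
    t = span[0] + np.arange(n) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * (t - span[0]) + phase)
    data = np.tile(x, (n_channels, n_trials, 1))
    return EpochSet(
        data=data,
        fs_hz=fs,
        times=t,
        trial_order=np.arange(1, n_trials + 1),
    )


@pytest.fixture()
def sine_epochs():
    return make_sine_epochs()


@pytest.fixture()
def noisefree_source_subject():
    """One noise-free 10.2 Hz source with tight jitter; known ground truth."""
    cfg = CohortConfig(
        sources=[SourceSpec(centre_freq_hz=10.2, bandwidth_hz=1e-6, base_amplitude=1.0)],
        n_subjects=1,
        n_trials=12,
        n_channels=12,
        noise_amplitude=0.0,
        seed=5,
    )
    return generate_subject(cfg, 0)
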