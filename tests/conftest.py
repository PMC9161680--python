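import numpy as np
import pytest

from thetaburst import simulate
from thetaburst.io import ChannelInfo, Recording


@pytest.fixture(scope="session")
def small_session():
    """One synthetic session with a strong 3-channel response, reused across tests."""
    schedule = simulate.generate_schedule([3, 4, 5, 6, 7, 8], trials_per_freq=10, seed=11)
    config = simulate.SimulationConfig(
        n_channels=4, response_gain=np.array([0.0, 3.0, 3.0, 3.0]), seed=12
    )
    rec, truth = simulate.synthesize_recording(config, schedule)
    return rec, schedule, truth


@pytest.fixture()
def noise_recording():
    """Plain multichannel pink-noise recording, 60 s at 250 Hz."""
    rng = np.random.default_rng(7)
    fs = 250.0
    n = int(60 * fs)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** -0.5
    sig = np.fft.irfft(
        (rng.standard_normal((3, freqs.size)) + 1j * rng.standard_normal((3, freqs.size)))
        * shaping,
        n=n,
        axis=1,
    )
    sig /= sig.std(axis=1, keepdims=True)
    chans = [ChannelInfo(f"E{i}", (10.0 * i, 0.0, 0.0)) for i in range(3)]
    return Recording(sig, fs, chans)
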