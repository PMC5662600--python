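import numpy as np
import pytest

from ieegpac import SyntheticConfig, generate_sleep_recording

FS = 512.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def sleep_recording():
    """Two-channel 5-min NREM-like recording: one coupled, one uncoupled."""
    cfg = SyntheticConfig(n_channels=2, duration=300.0,
                          coupling_depth=(0.8, 0.0),
                          preferred_phase_deg=0.0, seed=0)
    return generate_sleep_recording(cfg)


@pytest.fixture(scope="session")
def pink_noise():
    """Pure 1/f background, 2 minutes, for detector false-positive checks."""
    from ieegpac.synthetic import _one_over_f_noise

    rng = np.random.default_rng(42)
    return _one_over_f_noise(rng, int(120 * FS), FS, 1.0, 15.0)
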