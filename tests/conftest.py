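import numpy as np
import pytest

from oculomap.events import GazeRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(x, y, pupil=None, rate=1000.0, px_per_deg=25.0, trial_id="t0"):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if pupil is None:
        pupil = np.full(len(x), 900.0)
    t = np.arange(len(x)) * (1000.0 / rate)
    return GazeRecording(trial_id, t, x, y, np.asarray(pupil, dtype=float),
                         rate=rate, px_per_deg=px_per_deg)


@pytest.fixture
def stationary_recording():
    """500 ms of perfectly still gaze with full pupil signal."""
    n = 500
    return make_recording(np.full(n, 100.0), np.full(n, 120.0))
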