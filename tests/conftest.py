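import numpy as np
import pytest

from lcsync import synthetic
from lcsync.datatypes import TimeSeriesMatrix

#: search boxes bracketing the default phantom's planted LC positions
LC_SEARCH = {"left": (34, 46, 34, 46), "right": (34, 46, 50, 62)}


@pytest.fixture
def noiseless_phantom():
    truth = synthetic.default_phantom_truth(noise_sd=0.0)
    volume, rois = synthetic.gen_nm_phantom(truth, seed=0)
    return truth, volume, rois


@pytest.fixture
def noisy_phantom():
    truth = synthetic.default_phantom_truth()
    volume, rois = synthetic.gen_nm_phantom(truth, seed=42)
    return truth, volume, rois


def make_ts(values: np.ndarray, tr: float = 2.0) -> TimeSeriesMatrix:
    values = np.atleast_2d(values)
    labels = [f"n{i}" for i in range(values.shape[0])]
    return TimeSeriesMatrix(values, labels, tr)


@pytest.fixture
def band_limited_ts():
    """33-node random band-limited (0.04-0.07 Hz) matrix, 195 points, TR 2 s."""

    def _make(seed: int) -> TimeSeriesMatrix:
        rng = np.random.default_rng(seed)
        n, t_len, tr = 33, 195, 2.0
        t = np.arange(t_len) * tr
        freqs = rng.uniform(0.04, 0.07, size=n)
        phases = rng.uniform(-np.pi, np.pi, size=n)
        amps = rng.uniform(0.5, 1.5, size=n)
        return make_ts(amps[:, None] * np.cos(2 * np.pi * freqs[:, None] * t + phases[:, None]), tr)

    return _make
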