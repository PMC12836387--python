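import numpy as np
import pytest

from hrv.series import BeatSeries, NNSeries


def build_nn(intervals_ms, t0: float = 0.0) -> NNSeries:
    """NN series with onsets implied by cumulative intervals (gap-free)."""
    iv = np.asarray(intervals_ms, dtype=float)
    return NNSeries(intervals=iv, onsets=t0 + np.cumsum(iv) / 1000.0)


def random_nn(rng: np.random.Generator, n: int = 700, mean: float = 500.0,
              sd: float = 40.0) -> NNSeries:
    """Random positive NN series long enough for spectral analysis."""
    iv = np.clip(mean + sd * rng.standard_normal(n), 250.0, None)
    return build_nn(iv)


def beats_from_times(times, labels=None, clock: str = "00:00") -> BeatSeries:
    times = np.asarray(times, dtype=float)
    if labels is None:
        labels = ["normal"] * len(times)
    return BeatSeries(times, np.asarray(labels, dtype=object), record_start_clock=clock)


@pytest.fixture
def make_nn():
    return build_nn


@pytest.fixture
def make_random_nn():
    return random_nn


@pytest.fixture
def make_beats():
    return beats_from_times
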