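"""Time-domain linear HRV indices: SDNN, RMSSD and mean heart rate.

SDNN uses the sample standard deviation (N-1 denominator); RMSSD divides by
the number of successive differences.  Successive differences are never
taken across a filtering gap, because the neighbours of a rejected beat are
not physiologically successive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import NNSeries


@dataclass(frozen=True)
class TimeDomainIndices:
    sdnn: float        # ms
    rmssd: float       # ms
    mean_hr: float     # bpm
    n_intervals: int


def sdnn(nn: NNSeries) -> float:
    """Sample standard deviation (ms) of all retained NN intervals."""
    if len(nn) < 2:
        raise ValueError("SDNN needs at least 2 NN intervals")
    return float(np.std(nn.intervals, ddof=1))


def _successive_diffs(nn: NNSeries) -> np.ndarray:
    parts = [np.diff(nn.intervals[run]) for run in nn.contiguous_runs()]
    parts = [p for p in parts if len(p)]
    return np.concatenate(parts) if parts else np.empty(0)


def rmssd(nn: NNSeries) -> float:
    """Root mean square (ms) of successive NN differences within gap-free runs."""
    if len(nn) < 2:
        raise ValueError("RMSSD needs at least 2 NN intervals")
    d = _successive_diffs(nn)
    if len(d) == 0:
        raise ValueError("RMSSD undefined: no gap-free successive pairs")
    return float(np.sqrt(np.mean(d ** 2)))


def mean_hr(nn: NNSeries) -> float:
    """Mean heart rate in beats per minute, 60000 / mean(NN ms)."""
    if len(nn) < 1:
        raise ValueError("mean HR needs at least 1 NN interval")
    return float(60000.0 / np.mean(nn.intervals))


def time_domain_indices(nn: NNSeries) -> TimeDomainIndices:
    return TimeDomainIndices(sdnn=sdnn(nn), rmssd=rmssd(nn),
                             mean_hr=mean_hr(nn), n_intervals=len(nn))
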