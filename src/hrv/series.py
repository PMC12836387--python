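"""Core containers for beat-event and NN-interval series.

A :class:`BeatSeries` is the raw substrate emitted by a Holter annotator (or
by the simulator): beat times in seconds from record start plus a per-beat
label.  A :class:`NNSeries` is what every HRV index consumes: the retained
normal-to-normal intervals in milliseconds, with the onset time (time of the
interval's terminating beat) kept so that filtering gaps remain visible to
downstream modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Recognised beat labels.
BEAT_LABELS = ("normal", "ectopic", "artifact", "unknown")

#: Tolerance (ms) when deciding whether two retained intervals are contiguous.
_GAP_TOL_MS = 1e-6


def parse_clock(clock: str) -> int:
    """Parse ``"HH:MM"`` into seconds after midnight."""
    parts = clock.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"clock time must be HH:MM, got {clock!r}")
    hh, mm = int(parts[0]), int(parts[1])
    if not (0 <= hh < 24 and 0 <= mm < 60):
        raise ValueError(f"clock time out of range: {clock!r}")
    return 3600 * hh + 60 * mm


@dataclass(frozen=True)
class BeatSeries:
    """Timestamped heartbeat events with per-beat labels.

    Parameters
    ----------
    times
        Beat times in seconds from record start, strictly increasing.
    labels
        One of ``normal``, ``ectopic``, ``artifact``, ``unknown`` per beat.
    record_start_clock
        Wall-clock ``HH:MM`` of the first recorded second; used by the
        sleep-window selector to convert elapsed time to clock time.
    """

    times: np.ndarray
    labels: np.ndarray
    record_start_clock: str = "00:00"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        if times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if len(labels) != len(times):
            raise ValueError("labels must match times in length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise ValueError(f"beat times not strictly increasing at index {bad}")
        bad_labels = set(labels) - set(BEAT_LABELS)
        if bad_labels:
            raise ValueError(f"unrecognised beat labels: {sorted(bad_labels)}")
        parse_clock(self.record_start_clock)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.times)

    def shifted(self, offset_s: float, record_start_clock: str | None = None) -> "BeatSeries":
        """Return a copy with all beat times shifted by ``offset_s`` seconds."""
        return replace(
            self,
            times=self.times + offset_s,
            record_start_clock=record_start_clock or self.record_start_clock,
        )


@dataclass(frozen=True)
class NNSeries:
    """Normal-to-normal intervals (ms) with onset times.

    ``onsets[i]`` is the time (s from record start) of the beat terminating
    ``intervals[i]``.  Rejected intervals leave gaps: wherever
    ``onsets[i] - onsets[i-1]`` does not equal ``intervals[i]`` the retained
    sequence is not physiologically contiguous, and successive-difference
    statistics (RMSSD, Poincare pairs, PRSA windows) must not bridge it.
    """

    intervals: np.ndarray
    onsets: np.ndarray
    n_rejected: int = 0
    window: tuple | None = None

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        onsets = np.asarray(self.onsets, dtype=float)
        if intervals.shape != onsets.shape or intervals.ndim != 1:
            raise ValueError("intervals and onsets must be 1-D arrays of equal length")
        if np.any(intervals <= 0):
            raise ValueError("NN intervals must be positive")
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        object.__setattr__(self, "intervals", intervals)
        object.__setattr__(self, "onsets", onsets)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def gap_before(self) -> np.ndarray:
        """Boolean array: ``gap_before[i]`` is True when interval ``i`` does not
        start where interval ``i-1`` ended (always False for ``i = 0``)."""
        out = np.zeros(len(self), dtype=bool)
        if len(self) > 1:
            dt_ms = np.diff(self.onsets) * 1000.0
            out[1:] = np.abs(dt_ms - self.intervals[1:]) > _GAP_TOL_MS
        return out

    def contiguous_runs(self) -> list[slice]:
        """Slices of maximal gap-free runs of retained intervals."""
        if len(self) == 0:
            return []
        starts = np.flatnonzero(self.gap_before)
        edges = np.concatenate(([0], starts, [len(self)]))
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]

    def to_beat_series(self, record_start_clock: str = "00:00") -> BeatSeries:
        """Reconstruct the surviving beats (all relabelled ``normal``).

        Each retained interval contributes its two endpoint beats; shared
        endpoints inside a contiguous run are emitted once.
        """
        times: list[float] = []
        for run in self.contiguous_runs():
            onsets = self.onsets[run]
            first_start = onsets[0] - self.intervals[run][0] / 1000.0
            times.append(first_start)
            times.extend(onsets.tolist())
        arr = np.asarray(times)
        return BeatSeries(arr, np.array(["normal"] * len(arr), dtype=object),
                          record_start_clock=record_start_clock)


@dataclass(frozen=True)
class FilterRules:
    """Beat/interval rejection rules used to reduce raw beats to NN intervals.

    Defaults are generous physiologic bounds for dogs with marked respiratory
    sinus arrhythmia; every field is configurable.
    """

    min_ms: float = 200.0
    max_ms: float = 2000.0
    max_rel_step: float = 0.25
    drop_nonnormal: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_ms < self.max_ms):
            raise ValueError("require 0 < min_ms < max_ms")
        if not (0 < self.max_rel_step <= 1):
            raise ValueError("max_rel_step must lie in (0, 1]")
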