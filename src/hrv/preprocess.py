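"""Beat-record input, sleep-window selection and NN-interval filtering.

Holter systems annotate beats; HRV indices want clean normal-to-normal (NN)
intervals from a defined nocturnal window.  This module covers the three
steps between: reading beat/RR records, restricting to a wall-clock window
(by default midnight of the first night through 08:00 of the second day),
and rejecting intervals adjacent to non-normal beats or with implausible
values or steps.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .series import BeatSeries, FilterRules, NNSeries, parse_clock

_DAY_S = 86400


def read_beats(path, record_start_clock: str = "00:00") -> BeatSeries:
    """Read a beat annotation CSV (header ``time_s,label``) or a plain RR
    list (one interval in ms per line, converted to cumulative beat times
    with all labels ``normal``).  The two dialects are told apart by the
    header line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty beat record")
    first = text.lstrip().splitlines()[0]
    if first.replace(" ", "").lower().startswith("time_s"):
        df = pd.read_csv(io.StringIO(text))
        times = df["time_s"].to_numpy(dtype=float)
        labels = df["label"].astype(str).str.strip().to_numpy(dtype=object)
        steps = np.diff(times)
        if np.any(steps <= 0):
            row = int(np.flatnonzero(steps <= 0)[0]) + 1
            raise ValueError(f"{path}: beat times not strictly increasing at data row {row}")
        return BeatSeries(times, labels, record_start_clock=record_start_clock)
    rr_ms = np.loadtxt(io.StringIO(text), dtype=float, ndmin=1)
    if np.any(rr_ms <= 0):
        row = int(np.flatnonzero(rr_ms <= 0)[0])
        raise ValueError(f"{path}: non-positive RR interval at data row {row}")
    times = np.cumsum(rr_ms) / 1000.0
    labels = np.array(["normal"] * len(times), dtype=object)
    return BeatSeries(times, labels, record_start_clock=record_start_clock)


def write_beats(beats: BeatSeries, path) -> None:
    """Write the beat CSV dialect consumed by :func:`read_beats`."""
    pd.DataFrame({"time_s": beats.times, "label": beats.labels}).to_csv(path, index=False)


def write_rr(beats: BeatSeries, path) -> None:
    """Export successive RR intervals as plain text, one ms value per line."""
    np.savetxt(path, np.diff(beats.times) * 1000.0, fmt="%.6f")


def clock_to_elapsed(record_start_clock: str, clock: str, day_index: int) -> float:
    """Seconds from record start to clock time ``clock`` on day ``day_index``,
    where day indices count midnights after record start (day 0 is the
    calendar day the record begins)."""
    if day_index < 0:
        raise ValueError("day_index must be >= 0")
    return day_index * _DAY_S + parse_clock(clock) - parse_clock(record_start_clock)


def select_window(
    beats: BeatSeries,
    start_clock: str = "00:00",
    end_clock: str = "08:00",
    start_day_index: int = 1,
    end_day_index: int = 2,
    nightly: bool = False,
) -> BeatSeries:
    """Retain beats whose wall-clock time lies in the analysis window.

    The window is half-open ``[start, end)`` in wall-clock terms.  The
    default (midnight of day 1 through 08:00 of day 2) is the contiguous
    nocturnal span of a 48-h recording started during day 0.  With
    ``nightly=True`` the same clock window is applied separately on each day
    from ``start_day_index`` through ``end_day_index`` and the selections are
    united, leaving daytime gaps between the nightly blocks.
    """
    t = beats.times
    if nightly:
        mask = np.zeros(len(t), dtype=bool)
        for day in range(start_day_index, end_day_index + 1):
            lo = clock_to_elapsed(beats.record_start_clock, start_clock, day)
            hi = clock_to_elapsed(beats.record_start_clock, end_clock, day)
            mask |= (t >= lo) & (t < hi)
    else:
        lo = clock_to_elapsed(beats.record_start_clock, start_clock, start_day_index)
        hi = clock_to_elapsed(beats.record_start_clock, end_clock, end_day_index)
        mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise ValueError(
            "window selection is empty: check the window clocks/day indices "
            "against the record start clock and duration"
        )
    return BeatSeries(t[mask], beats.labels[mask],
                      record_start_clock=beats.record_start_clock)


def filter_nn(beats: BeatSeries, rules: FilterRules = FilterRules(),
              window: tuple | None = None) -> NNSeries:
    """Reduce a beat series to retained NN intervals.

    An interval is rejected when (with ``drop_nonnormal``) either endpoint
    beat is non-normal, when it falls outside ``[min_ms, max_ms]``, or when
    its relative step from the previously *retained* interval exceeds
    ``max_rel_step``.  Rejections leave gaps (no interpolation here): onset
    times of retained intervals are kept so downstream modules can refuse to
    bridge them.
    """
    if len(beats) < 3:
        raise ValueError("need at least 3 beats to form an NN series")
    t = beats.times
    lab = beats.labels
    iv = np.diff(t) * 1000.0
    normal = lab == "normal"
    ok = np.ones(len(iv), dtype=bool)
    if rules.drop_nonnormal:
        ok &= normal[:-1] & normal[1:]
    ok &= (iv >= rules.min_ms) & (iv <= rules.max_ms)

    keep = np.zeros(len(iv), dtype=bool)
    prev = None
    for i in range(len(iv)):
        if not ok[i]:
            continue
        if prev is not None and abs(iv[i] - prev) / prev > rules.max_rel_step:
            continue
        keep[i] = True
        prev = iv[i]

    n_rejected = int(len(iv) - keep.sum())
    if keep.sum() < 2:
        raise ValueError("insufficient NN data after filtering")
    return NNSeries(intervals=iv[keep], onsets=t[1:][keep],
                    n_rejected=n_rejected, window=window)


def write_nn(nn: NNSeries, path) -> None:
    """Write the retained NN intervals as CSV (``onset_s,nn_ms``)."""
    pd.DataFrame({"onset_s": nn.onsets, "nn_ms": nn.intervals}).to_csv(path, index=False)
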