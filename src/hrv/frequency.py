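"""Frequency-domain HRV: tachogram resampling, PSD estimation, band powers.

The NN tachogram is unevenly sampled in time, so band integration first
resamples it onto a uniform grid (cubic spline, default 4 Hz, linear
detrend).  The default estimator is the full-record rectangular-window
periodogram, for which discrete Parseval holds exactly; a Welch option
(600-s Hann segments, 50% overlap) trades that exactness for variance
reduction.  Band edges follow the usual partition of 0-0.4 Hz into
ULF / VLF / LF / HF, with half-open bands ``[lo, hi)`` so shared edges are
assigned deterministically; normalised indices are nHF = HF/(LF+HF),
nLF = LF/(LF+HF) and the LF/HF ratio.

Because ULF (below 0.00333 Hz) needs the full record's frequency resolution,
Welch mode reports ULF from a full-record periodogram and the upper bands
from Welch; this hybrid is recorded in the indices' ``method`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .series import NNSeries

#: Default band edges (Hz): ULF, VLF, LF, HF partition of 0-0.4 Hz.
DEFAULT_BAND_EDGES = (0.0, 0.00333, 0.04, 0.15, 0.4)

#: Onset spacing (s) above which the spline is replaced by a linear bridge.
MAX_SPLINE_GAP_S = 5.0

_MIN_SPAN_S = 300.0
_WELCH_SEGMENT_S = 600.0


@dataclass(frozen=True)
class EvenTachogram:
    """Uniformly resampled NN tachogram."""

    fs: float                 # Hz
    values: np.ndarray        # ms
    t0: float                 # s, time of the first sample
    detrended: bool
    bridged_gaps: tuple = ()  # (start_s, end_s) spans linearly bridged

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tachogram values must be finite")


@dataclass(frozen=True)
class PSD:
    freqs: np.ndarray         # Hz, uniform ascending grid from 0
    density: np.ndarray       # ms^2/Hz, one-sided

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class SpectralIndices:
    """Band powers (ms^2) and the normalised/ratio indices.

    ``n_hf``, ``n_lf`` and ``lf_hf`` are dimensionless; they are NaN when the
    denominator band power is zero.  ``tp`` is the sum of the four bands, so
    band additivity holds by construction.
    """

    tp: float
    ulf: float
    vlf: float
    lf: float
    hf: float
    n_hf: float
    n_lf: float
    lf_hf: float
    band_edges: tuple = DEFAULT_BAND_EDGES
    method: str = "periodogram"


def resample_tachogram(
    nn: NNSeries,
    fs: float = 4.0,
    detrend: bool = True,
    max_gap_s: float = MAX_SPLINE_GAP_S,
) -> EvenTachogram:
    """Interpolate the (onset, interval) tachogram onto a uniform grid.

    Cubic-spline interpolation everywhere except across onset gaps longer
    than ``max_gap_s``, which are linearly bridged (a spline through a long
    gap can overshoot wildly); bridged spans are recorded on the result.
    """
    if len(nn) < 3:
        raise ValueError("resampling needs at least 3 NN intervals")
    if fs <= 0.8:
        raise ValueError("sampling rate must exceed 0.8 Hz (= 2 x 0.4 Hz)")
    onsets, intervals = nn.onsets, nn.intervals
    span = onsets[-1] - onsets[0]
    if span < _MIN_SPAN_S:
        raise ValueError(f"record span {span:.1f} s is shorter than {_MIN_SPAN_S:.0f} s")
    grid = onsets[0] + np.arange(int(np.floor(span * fs)) + 1) / fs
    values = CubicSpline(onsets, intervals)(grid)

    bridged: list[tuple[float, float]] = []
    gaps = np.flatnonzero(np.diff(onsets) > max_gap_s)
    for g in gaps:
        lo, hi = onsets[g], onsets[g + 1]
        inside = (grid > lo) & (grid < hi)
        if inside.any():
            frac = (grid[inside] - lo) / (hi - lo)
            values[inside] = intervals[g] + frac * (intervals[g + 1] - intervals[g])
        bridged.append((float(lo), float(hi)))
    if detrend:
        values = sps.detrend(values, type="linear")
    return EvenTachogram(fs=fs, values=values, t0=float(grid[0]),
                         detrended=detrend, bridged_gaps=tuple(bridged))


def estimate_psd(tachogram: EvenTachogram, method: str = "periodogram") -> PSD:
    """One-sided PSD (ms^2/Hz) of the resampled tachogram.

    ``periodogram`` uses a rectangular window over the full record, so
    ``sum(density) * df`` equals the mean square of the signal exactly.
    ``welch`` averages 600-s Hann segments with 50% overlap.
    """
    x, fs = tachogram.values, tachogram.fs
    if method == "periodogram":
        freqs, dens = sps.periodogram(x, fs=fs, window="boxcar",
                                      detrend=False, scaling="density")
    elif method == "welch":
        nperseg = min(int(_WELCH_SEGMENT_S * fs), len(x))
        freqs, dens = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                                noverlap=nperseg // 2, detrend=False,
                                scaling="density")
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    return PSD(freqs=freqs, density=dens)


def band_powers(psd: PSD, edges=DEFAULT_BAND_EDGES, method: str = "periodogram") -> SpectralIndices:
    """Integrate the PSD over the ULF/VLF/LF/HF partition.

    Each band power is the rectangle-rule sum of ``density * df`` over bins
    whose centre frequency lies in the half-open band ``[lo, hi)``; TP is the
    sum of the four bands.
    """
    edges = tuple(edges)
    if len(edges) != 5 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be 5 ascending values (ULF/VLF/LF/HF partition)")
    if edges[-1] > psd.freqs[-1] + 1e-12:
        raise ValueError("top band edge exceeds the Nyquist frequency")
    df = psd.df
    powers = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (psd.freqs >= lo) & (psd.freqs < hi)
        powers.append(float(psd.density[mask].sum() * df))
    ulf, vlf, lf, hf = powers
    tp = ulf + vlf + lf + hf
    denom = lf + hf
    n_hf = hf / denom if denom > 0 else float("nan")
    n_lf = lf / denom if denom > 0 else float("nan")
    lf_hf = lf / hf if hf > 0 else float("nan")
    return SpectralIndices(tp=tp, ulf=ulf, vlf=vlf, lf=lf, hf=hf,
                           n_hf=n_hf, n_lf=n_lf, lf_hf=lf_hf,
                           band_edges=edges, method=method)


def spectral_indices(
    nn: NNSeries,
    fs: float = 4.0,
    method: str = "periodogram",
    edges=DEFAULT_BAND_EDGES,
) -> SpectralIndices:
    """Resample, estimate the PSD and integrate the bands in one call.

    In Welch mode the ULF band is taken from a full-record periodogram of
    the same tachogram (Welch segments cannot resolve it) and the result is
    labelled ``welch+periodogram-ulf``.
    """
    tach = resample_tachogram(nn, fs=fs)
    if method == "welch":
        upper = band_powers(estimate_psd(tach, "welch"), edges, method)
        full = band_powers(estimate_psd(tach, "periodogram"), edges, method)
        ulf = full.ulf
        tp = ulf + upper.vlf + upper.lf + upper.hf
        return SpectralIndices(tp=tp, ulf=ulf, vlf=upper.vlf, lf=upper.lf,
                               hf=upper.hf, n_hf=upper.n_hf, n_lf=upper.n_lf,
                               lf_hf=upper.lf_hf, band_edges=tuple(edges),
                               method="welch+periodogram-ulf")
    return band_powers(estimate_psd(tach, method), edges, method)


def write_psd(psd: PSD, path) -> None:
    """Export the PSD as CSV (``freq_hz,density_ms2_per_hz``)."""
    import pandas as pd

    pd.DataFrame({"freq_hz": psd.freqs, "density_ms2_per_hz": psd.density}
                 ).to_csv(path, index=False)
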