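"""Poincare plot descriptors SD1, SD2 and their ratio indices.

The Poincare plot scatters each NN interval against its successor.  SD1 is
the dispersion transverse to the identity line (beat-to-beat, vagally
mediated variability); SD2 is the dispersion along the identity-line
direction about the centroid (longer-term variability).  Their ratio tracks
sympathovagal balance: SD1/SD2 falls and SD2/SD1 rises under sympathetic
predominance.

Both axes use the population variance (denominator = number of pairs), so
the projection definitions agree exactly with the closed forms
``sd1^2 = Var(y - x)/2`` and ``sd2^2 = Var(x + y)/2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import NNSeries

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class PoincareIndices:
    sd1: float          # ms, width of the ellipse
    sd2: float          # ms, length of the ellipse
    sd1_sd2: float      # dimensionless; NaN when sd2 == 0
    sd2_sd1: float      # dimensionless; NaN when sd1 == 0
    n_pairs: int
    mean_rr: float      # ms, mean over all pair coordinates


def poincare_pairs(nn: NNSeries) -> tuple[np.ndarray, np.ndarray]:
    """Successor pairs ``(x_i, y_i) = (NN_i, NN_{i+1})``.

    Pairs spanning a filtering gap are excluded: a rejected beat's neighbours
    are not successive.
    """
    if len(nn) < 3:
        raise ValueError("Poincare analysis needs at least 3 NN intervals")
    xs, ys = [], []
    for run in nn.contiguous_runs():
        iv = nn.intervals[run]
        if len(iv) >= 2:
            xs.append(iv[:-1])
            ys.append(iv[1:])
    if not xs:
        raise ValueError("fewer than 2 Poincare pairs after gap exclusion")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 2:
        raise ValueError("fewer than 2 Poincare pairs after gap exclusion")
    return x, y


def sd1_sd2(nn: NNSeries) -> PoincareIndices:
    """SD1/SD2 ellipse descriptors from the successor-pair cloud.

    Signed transverse distances ``d1 = (y - x)/sqrt(2)`` give SD1; the
    longitudinal coordinates ``d2 = (x + y - 2m)/sqrt(2)`` about the grand
    mean ``m`` of all pair coordinates give SD2.
    """
    x, y = poincare_pairs(nn)
    m = float((x.mean() + y.mean()) / 2.0)
    d1 = (y - x) / _SQRT2
    d2 = (x + y - 2.0 * m) / _SQRT2
    sd1 = float(np.std(d1))
    sd2 = float(np.std(d2))
    return PoincareIndices(
        sd1=sd1,
        sd2=sd2,
        sd1_sd2=sd1 / sd2 if sd2 > 0 else float("nan"),
        sd2_sd1=sd2 / sd1 if sd1 > 0 else float("nan"),
        n_pairs=len(x),
        mean_rr=m,
    )


def write_pairs(nn: NNSeries, path) -> None:
    """Export the pair cloud as CSV (``rr_n_ms,rr_n1_ms``) for scatter plots."""
    import pandas as pd

    x, y = poincare_pairs(nn)
    pd.DataFrame({"rr_n_ms": x, "rr_n1_ms": y}).to_csv(path, index=False)
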