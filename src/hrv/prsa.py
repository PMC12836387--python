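"""Phase-rectified signal averaging (PRSA): AC and DC.

PRSA aligns windows of the NN series at anchors where the rhythm slows
(deceleration) or quickens (acceleration), averages them into a
phase-rectified curve X(k), and summarises the curve by a Haar-like
quarter-sum contrast around the anchor:

    capacity = [X(0) + X(1) - X(-1) - X(-2)] / 4

reported as deceleration capacity (DC, normally positive) or acceleration
capacity (AC, normally negative).  Anchors whose +-L-beat window would span
a filtering gap are excluded; phase alignment across a gap is meaningless.
Defaults (L = 5, relative anchor threshold 1.05, single-scale contrast)
follow the standard form of the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import NNSeries


@dataclass(frozen=True)
class PRSAConfig:
    half_window: int = 5               # L, beats on each side of the anchor
    anchor_mode: str = "deceleration"  # or "acceleration"
    rel_threshold: float = 1.05        # max relative step accepted as an anchor

    def __post_init__(self) -> None:
        if self.half_window < 2:
            raise ValueError("half_window L must be >= 2 (the capacity "
                             "contrast needs X(-2)..X(1))")
        if self.anchor_mode not in ("deceleration", "acceleration"):
            raise ValueError("anchor_mode must be 'deceleration' or 'acceleration'")
        if self.rel_threshold <= 1:
            raise ValueError("rel_threshold must exceed 1")


@dataclass(frozen=True)
class PRSAIndices:
    ks: np.ndarray         # phase offsets, -L .. L-1 with the anchor at 0
    curve: np.ndarray      # X(k), ms
    capacity: float        # ms; DC in deceleration mode, AC in acceleration mode
    n_anchors: int
    anchor_mode: str


def find_anchors(nn: NNSeries, cfg: PRSAConfig = PRSAConfig()) -> np.ndarray:
    """Indices i of valid anchors (into ``nn.intervals``).

    Deceleration anchors satisfy ``NN_{i-1} < NN_i <= thr * NN_{i-1}``;
    acceleration anchors ``NN_{i-1}/thr <= NN_i < NN_{i-1}``.  Ties are
    anchors in neither mode.  An anchor needs L intervals before and L-1
    after it inside the same gap-free run.
    """
    L = cfg.half_window
    out: list[np.ndarray] = []
    for run in nn.contiguous_runs():
        iv = nn.intervals[run]
        n = len(iv)
        if n < 2 * L:
            continue
        cur, prev = iv[1:], iv[:-1]
        if cfg.anchor_mode == "deceleration":
            cond = (cur > prev) & (cur <= cfg.rel_threshold * prev)
        else:
            cond = (cur < prev) & (cur >= prev / cfg.rel_threshold)
        local = np.flatnonzero(cond) + 1       # index of the anchor interval
        local = local[(local >= L) & (local + L - 1 <= n - 1)]
        out.append(local + run.start)
    return np.concatenate(out).astype(int) if out else np.empty(0, dtype=int)


def prsa_curve(nn: NNSeries, anchors: np.ndarray, cfg: PRSAConfig = PRSAConfig()) -> PRSAIndices:
    """Phase-rectified average X(k) = mean over anchors of NN_{i+k}."""
    anchors = np.asarray(anchors, dtype=int)
    if len(anchors) == 0:
        raise ValueError("no anchors: PRSA curve undefined")
    L = cfg.half_window
    ks = np.arange(-L, L)
    windows = nn.intervals[anchors[:, None] + ks[None, :]]
    curve = windows.mean(axis=0)
    return PRSAIndices(ks=ks, curve=curve, capacity=_capacity(ks, curve),
                       n_anchors=len(anchors), anchor_mode=cfg.anchor_mode)


def _capacity(ks: np.ndarray, curve: np.ndarray) -> float:
    x = {int(k): float(v) for k, v in zip(ks, curve)}
    return (x[0] + x[1] - x[-1] - x[-2]) / 4.0


def capacity(indices: PRSAIndices) -> float:
    """Quarter-sum contrast of the PRSA curve around the anchor (ms)."""
    return _capacity(indices.ks, indices.curve)


def prsa_indices(nn: NNSeries, cfg: PRSAConfig = PRSAConfig()) -> PRSAIndices:
    """Anchor search, phase-rectified averaging and capacity in one call."""
    return prsa_curve(nn, find_anchors(nn, cfg), cfg)


def write_curve(indices: PRSAIndices, path) -> None:
    """Export the PRSA curve as CSV (``k,x_k_ms``)."""
    import pandas as pd

    pd.DataFrame({"k": indices.ks, "x_k_ms": indices.curve}).to_csv(path, index=False)
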