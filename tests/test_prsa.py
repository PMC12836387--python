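"""PRSA anchor selection, phase-rectified averaging and capacities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hrv
from hrv.prsa import PRSAConfig, find_anchors, prsa_curve, prsa_indices
from hrv.series import NNSeries
from hrv.synthetic import AutonomicConfig


def brute_force_prsa(intervals, L, mode, thr):
    """Independent naive implementation: per-index condition scan and
    nested-loop averaging."""
    n = len(intervals)
    anchors = []
    for i in range(1, n):
        prev, cur = intervals[i - 1], intervals[i]
        if mode == "deceleration":
            is_anchor = prev < cur <= thr * prev
        else:
            is_anchor = prev / thr <= cur < prev
        if is_anchor and i - L >= 0 and i + L - 1 <= n - 1:
            anchors.append(i)
    if not anchors:
        return anchors, None, None
    curve = []
    for k in range(-L, L):
        curve.append(sum(intervals[i + k] for i in anchors) / len(anchors))
    x = dict(zip(range(-L, L), curve))
    cap = (x[0] + x[1] - x[-1] - x[-2]) / 4.0
    return anchors, np.array(curve), cap


def test_strictly_decreasing_series_has_no_deceleration_anchors(make_nn):
    nn = make_nn(np.arange(900.0, 500.0, -2.0))
    assert len(find_anchors(nn, PRSAConfig(anchor_mode="deceleration"))) == 0


def test_gentle_ramp_anchors_everywhere_in_range(make_nn):
    nn = make_nn(np.arange(500.0, 540.0, 2.0))  # 0.4% steps < 5% threshold
    anchors = find_anchors(nn, PRSAConfig(half_window=2))
    n = len(nn.intervals)
    assert anchors.tolist() == list(range(2, n - 1))


def test_ties_are_never_anchors(make_nn):
    nn = make_nn([500.0] * 20)
    for mode in ("deceleration", "acceleration"):
        assert len(find_anchors(nn, PRSAConfig(anchor_mode=mode))) == 0


def test_single_anchor_curve_is_the_raw_window(make_nn):
    iv = np.array([500, 500, 500, 500, 500, 510, 480, 470, 460, 450.0])
    nn = make_nn(iv)
    cfg = PRSAConfig(half_window=5)
    anchors = find_anchors(nn, cfg)
    assert anchors.tolist() == [5]
    out = prsa_curve(nn, anchors, cfg)
    assert np.allclose(out.curve, iv)


def test_ramp_curve_linear_and_capacity_equals_step(make_nn):
    step = 2.0
    nn = make_nn(np.arange(500.0, 700.0, step))
    out = prsa_indices(nn, PRSAConfig(half_window=5))
    slopes = np.diff(out.curve)
    assert np.allclose(slopes, step, atol=1e-9)
    assert out.capacity == pytest.approx(step, abs=1e-9)


def test_matches_bruteforce_on_random_series(make_nn):
    rng = np.random.default_rng(11)
    for trial in range(20):
        n = int(rng.integers(200, 800))
        iv = np.clip(550 + 60 * rng.standard_normal(n), 300, None)
        nn = make_nn(iv)
        for mode in ("deceleration", "acceleration"):
            cfg = PRSAConfig(half_window=5, anchor_mode=mode)
            anchors = find_anchors(nn, cfg)
            ref_anchors, ref_curve, ref_cap = brute_force_prsa(iv, 5, mode, 1.05)
            assert anchors.tolist() == ref_anchors
            if ref_anchors:
                out = prsa_curve(nn, anchors, cfg)
                assert np.allclose(out.curve, ref_curve, rtol=1e-12, atol=1e-12)
                assert out.capacity == pytest.approx(ref_cap, abs=1e-12)


def test_anchor_windows_do_not_span_gaps():
    iv = np.concatenate([500 + 10 * np.sin(np.arange(30)),
                         500 + 10 * np.sin(np.arange(30))])
    onsets = np.cumsum(iv) / 1000.0
    onsets[30:] += 5.0
    nn = NNSeries(intervals=iv, onsets=onsets)
    cfg = PRSAConfig(half_window=5)
    anchors = find_anchors(nn, cfg)
    # each anchor must keep L before and L-1 after inside its own run
    for a in anchors:
        run = 0 if a < 30 else 30
        assert a - 5 >= run and a + 4 <= run + 29


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    offset=st.floats(-200, 500),
    scale=st.floats(0.25, 4.0),
    seed=st.integers(0, 100),
)
def test_capacity_translation_and_scale_laws(offset, scale, seed):
    rng = np.random.default_rng(seed)
    iv = np.clip(600 + 50 * rng.standard_normal(300), 350, None)
    base = NNSeries(intervals=iv, onsets=np.cumsum(iv) / 1000.0)
    cfg = PRSAConfig()
    anchors = find_anchors(base, cfg)
    if len(anchors) == 0:
        return
    cap = prsa_curve(base, anchors, cfg).capacity
    shifted = NNSeries(intervals=iv + offset + 250,
                       onsets=np.cumsum(iv + offset + 250) / 1000.0)
    scaled = NNSeries(intervals=iv * scale, onsets=np.cumsum(iv * scale) / 1000.0)
    # the capacity contrast is translation invariant over a fixed anchor set
    cap_shift = prsa_curve(shifted, anchors, cfg).capacity
    assert cap_shift == pytest.approx(cap, rel=1e-9, abs=1e-9)
    # the relative anchor condition is scale invariant, and capacity scales
    anchors_scaled = find_anchors(scaled, cfg)
    assert np.array_equal(anchors_scaled, anchors)
    cap_scale = prsa_curve(scaled, anchors_scaled, cfg).capacity
    assert cap_scale == pytest.approx(scale * cap, rel=1e-9, abs=1e-9)


def test_vagal_preset_has_positive_dc_negative_ac():
    cfg = AutonomicConfig(duration=600)
    for seed in range(20):
        nn = hrv.filter_nn(hrv.generate_beats(cfg, seed))
        dc = prsa_indices(nn, PRSAConfig(anchor_mode="deceleration")).capacity
        ac = prsa_indices(nn, PRSAConfig(anchor_mode="acceleration")).capacity
        assert dc > 0
        assert ac < 0


def test_config_and_anchor_errors(make_nn):
    with pytest.raises(ValueError):
        PRSAConfig(half_window=1)
    with pytest.raises(ValueError):
        PRSAConfig(rel_threshold=0.9)
    nn = make_nn(np.arange(900.0, 500.0, -2.0))
    with pytest.raises(ValueError, match="no anchors"):
        prsa_curve(nn, np.empty(0, dtype=int), PRSAConfig())
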