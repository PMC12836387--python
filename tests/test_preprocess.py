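"""Record reading, sleep-window selection and NN filtering."""

import numpy as np
import pytest

import hrv
from hrv.preprocess import clock_to_elapsed, read_beats, select_window, filter_nn
from hrv.series import BeatSeries, FilterRules
from hrv.synthetic import ArtifactConfig, AutonomicConfig


# ---------------------------------------------------------------- read_beats

def test_read_beat_csv(tmp_path):
    p = tmp_path / "beats.csv"
    p.write_text("time_s,label\n0.5,normal\n1.0,normal\n1.6,normal\n")
    beats = read_beats(p)
    assert len(beats) == 3
    assert np.allclose(np.diff(beats.times) * 1000, [500, 600])


def test_read_plain_rr_list(tmp_path):
    p = tmp_path / "rr.txt"
    p.write_text("500\n500\n500\n")
    beats = read_beats(p)
    assert np.allclose(beats.times, [0.5, 1.0, 1.5])
    assert all(lab == "normal" for lab in beats.labels)


def test_read_nonmonotone_times_reports_row(tmp_path):
    p = tmp_path / "beats.csv"
    p.write_text("time_s,label\n0.5,normal\n1.0,normal\n0.9,normal\n")
    with pytest.raises(ValueError, match="row 2"):
        read_beats(p)


def test_read_empty_file_errors(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("")
    with pytest.raises(ValueError, match="empty"):
        read_beats(p)


# ------------------------------------------------------------- select_window

def test_window_clock_arithmetic(make_beats):
    # record starts 20:00; 00:00 of day 1 is 4 h elapsed, 08:00 is 12 h
    assert clock_to_elapsed("20:00", "00:00", 1) == 4 * 3600
    assert clock_to_elapsed("20:00", "08:00", 1) == 12 * 3600
    times = np.arange(0.5, 14 * 3600, 600.0)
    beats = make_beats(times, clock="20:00")
    sel = select_window(beats, "00:00", "08:00", 1, 1)
    assert sel.times.min() >= 4 * 3600
    assert sel.times.max() < 12 * 3600


def test_window_covering_whole_record_is_identity(make_beats):
    beats = make_beats(np.arange(0.5, 3600, 1.0))
    sel = select_window(beats, "00:00", "02:00", 0, 0)
    assert np.array_equal(sel.times, beats.times)


def test_zero_length_window_errors(make_beats):
    beats = make_beats(np.arange(0.5, 3600, 1.0))
    with pytest.raises(ValueError, match="empty"):
        select_window(beats, "01:00", "01:00", 0, 0)


def test_nightly_mode_selects_two_blocks(make_beats):
    times = np.arange(0.5, 40 * 3600, 1800.0)  # 40 h record from 20:00
    beats = make_beats(times, clock="20:00")
    sel = select_window(beats, "00:00", "08:00", 1, 2, nightly=True)
    elapsed = sel.times
    night1 = (elapsed >= 4 * 3600) & (elapsed < 12 * 3600)
    night2 = (elapsed >= 28 * 3600) & (elapsed < 36 * 3600)
    assert np.all(night1 | night2)
    assert night1.any() and night2.any()


def test_default_window_matches_32h_nocturnal_span(make_beats):
    times = np.arange(0.5, 48 * 3600, 3600.0)  # 48 h record from 10:00
    beats = make_beats(times, clock="10:00")
    sel = select_window(beats)  # 00:00 day 1 .. 08:00 day 2
    assert sel.times.min() >= 14 * 3600
    assert sel.times.max() < 46 * 3600


# ----------------------------------------------------------------- filter_nn

def test_clean_synthetic_series_has_no_rejections():
    beats = hrv.generate_beats(AutonomicConfig(duration=600), 0)
    nn = filter_nn(beats)
    assert nn.n_rejected == 0
    assert len(nn) == len(beats) - 1


def test_value_rules_reject_out_of_range_intervals(make_beats):
    times = np.cumsum([0, 0.5, 0.5, 0.1, 0.5, 0.5, 2.5, 0.5, 0.5])
    beats = make_beats(times)
    nn = filter_nn(beats, FilterRules(max_rel_step=1.0))
    assert nn.n_rejected == 2  # the 100 ms and the 2500 ms interval
    assert np.all((nn.intervals >= 200) & (nn.intervals <= 2000))


def test_injected_ectopics_are_rejected_against_ground_truth():
    """Over 50 seeds, >=90% of intervals adjacent to an injected ectopic
    must be rejected by the default rules."""
    cfg = AutonomicConfig(mean_rr=500, duration=500)
    art = ArtifactConfig(ectopic_rate=0.01)
    rejected = perturbed = 0
    for s in range(50):
        dirty = hrv.inject_artifacts(hrv.generate_beats(cfg, s), art, 100 + s)
        nn = filter_nn(dirty)
        kept = set(np.round(nn.onsets, 9))
        onsets = np.round(dirty.times[1:], 9)
        ect = np.flatnonzero(dirty.labels == "ectopic")
        idx = {j for i in ect for j in (i - 1, i) if 0 <= j < len(onsets)}
        perturbed += len(idx)
        rejected += sum(onsets[j] not in kept for j in idx)
    assert perturbed > 100
    assert rejected / perturbed >= 0.90


def test_value_rules_alone_keep_rmssd_near_clean():
    """Blinded to labels, the value/step rules still keep RMSSD within 5%
    of the uncontaminated series."""
    cfg = AutonomicConfig(duration=1200)
    art = ArtifactConfig(ectopic_rate=0.01)
    for s in range(3):
        clean = hrv.generate_beats(cfg, s)
        dirty = hrv.inject_artifacts(clean, art, 50 + s)
        blind = BeatSeries(dirty.times,
                           np.array(["normal"] * len(dirty), dtype=object))
        r_clean = hrv.rmssd(filter_nn(clean))
        r_blind = hrv.rmssd(filter_nn(blind))
        assert abs(r_blind - r_clean) / r_clean < 0.05


def test_all_nonnormal_beats_is_insufficient(make_beats):
    beats = make_beats([0.5, 1.0, 1.5, 2.0], labels=["artifact"] * 4)
    with pytest.raises(ValueError, match="insufficient NN data"):
        filter_nn(beats)


def test_filtering_commutes_with_time_origin_shift():
    beats = hrv.inject_artifacts(
        hrv.generate_beats(AutonomicConfig(duration=900), 4),
        ArtifactConfig(ectopic_rate=0.02), 5)
    # same physical record re-referenced to a start 90 min earlier: the wall
    # clock 00:10 now falls on day 1 (one midnight after the 22:30 start)
    shift_s = 90 * 60
    moved = beats.shifted(shift_s, record_start_clock="22:30")
    a = filter_nn(select_window(beats, "00:10", "00:20", 0, 0))
    b = filter_nn(select_window(moved, "00:10", "00:20", 1, 1))
    # identical up to the float rounding of the shifted beat times
    assert np.allclose(a.intervals, b.intervals, atol=1e-6)
    assert np.allclose(b.onsets - a.onsets, shift_s)
    assert a.n_rejected == b.n_rejected


def test_filter_is_idempotent_on_its_own_output():
    beats = hrv.inject_artifacts(
        hrv.generate_beats(AutonomicConfig(duration=900), 1),
        ArtifactConfig(ectopic_rate=0.02, missed_rate=0.01), 2)
    nn1 = filter_nn(beats)
    assert nn1.n_rejected > 0
    nn2 = filter_nn(nn1.to_beat_series())
    assert np.allclose(nn2.intervals, nn1.intervals)
    assert np.allclose(nn2.onsets, nn1.onsets)
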