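"""Spindle / K-complex detectors: statistic, duration rules, refractory, gates."""

import numpy as np
import pytest

from spindlekit.core_io import Recording
from spindlekit.detect import (
    DetectionConfig,
    DetectionThresholds,
    detect_kcomplexes,
    detect_recording,
    detect_spindles,
    spindle_statistic,
)
from spindlekit.synth import make_kcomplex_waveform, make_spindle_waveform

FS = 128.0


def test_statistic_zero_signal():
    assert np.all(spindle_statistic(np.zeros(1024), FS) == 0)


def test_statistic_steady_tone_mean_square():
    a = 12.0
    x = a * np.sin(2 * np.pi * 13.0 * np.arange(4096) / FS)
    stat = spindle_statistic(x, FS)
    mid = stat[1024:-1024]
    assert np.median(mid) == pytest.approx(a * a / 2.0, rel=0.05)


def test_statistic_attenuates_out_of_band_tone():
    t = np.arange(4096) / FS
    in_band = spindle_statistic(np.sin(2 * np.pi * 13.0 * t), FS)
    out_band = spindle_statistic(np.sin(2 * np.pi * 30.0 * t), FS)
    ratio_db = 10.0 * np.log10(np.median(in_band[1024:-1024]) /
                               np.median(out_band[1024:-1024]))
    assert ratio_db >= 20.0


def test_statistic_rejects_low_sampling_rate():
    with pytest.raises(ValueError):
        spindle_statistic(np.zeros(256), 50.0)


def test_spindle_burst_detected_with_high_overlap():
    x = np.zeros(int(20 * FS))
    w = make_spindle_waveform(FS, 13.0, 1.0, 40.0)
    i0 = int(8.0 * FS)
    x[i0:i0 + len(w)] += w
    events = detect_spindles(x, FS, thr=20.0)
    assert len(events) == 1
    ev = events[0]
    inter = min(ev.offset, 9.0) - max(ev.onset, 8.0)
    union = max(ev.offset, 9.0) - min(ev.onset, 8.0)
    assert inter / union >= 0.8
    assert ev.mean_freq == pytest.approx(13.0, abs=0.5)


def _rect_statistic(n_true: int, total: int = 4096, level: float = 100.0):
    """Rectangular statistic run of n_true samples; zero elsewhere, so the
    hysteresis extension cannot grow the run."""
    stat = np.zeros(total)
    stat[1000:1000 + n_true] = level
    return stat


@pytest.mark.parametrize("n,expected", [
    (int(0.3 * FS), 0),            # 0.3 s candidate never returned
    (int(round(0.5 * FS)) - 1, 0),  # just below the minimum duration
    (int(round(0.5 * FS)), 1),      # boundary accepts at exactly 0.5 s
    (int(1.0 * FS), 1),
])
def test_minimum_duration_boundary(n, expected):
    stat = _rect_statistic(n)
    events = detect_spindles(np.zeros(len(stat)), FS, thr=50.0, statistic=stat)
    assert len(events) == expected


def test_overlong_run_truncated_and_flagged():
    stat = _rect_statistic(int(5.0 * FS))
    (ev,) = detect_spindles(np.zeros(len(stat)), FS, thr=50.0, statistic=stat)
    assert ev.truncated
    assert ev.duration == pytest.approx(3.0, abs=1.0 / FS)


def test_threshold_above_statistic_max_gives_no_events():
    stat = _rect_statistic(int(1.0 * FS))
    assert detect_spindles(np.zeros(len(stat)), FS, thr=1e6, statistic=stat) == []


def test_close_runs_merge_across_small_gaps():
    stat = np.zeros(4096)
    stat[1000:1000 + 64] = 100.0   # 0.5 s at 128 Hz
    gap = int(0.15 * FS)
    stat[1000 + 64 + gap:1000 + 64 + gap + 64] = 100.0
    events = detect_spindles(np.zeros(len(stat)), FS, thr=50.0, statistic=stat)
    assert len(events) == 1


def test_kcomplex_window_convention():
    fs = 128.0
    x = np.zeros(int(20 * fs))
    w = make_kcomplex_waveform(fs, 160.0)   # negative peak ~ -88 µV
    peak_in_w = int(np.argmin(w))
    i0 = int(10.0 * fs) - peak_in_w         # negative peak lands at t=10.0 s
    x[i0:i0 + len(w)] += w
    (ev,) = detect_kcomplexes(x, fs, thr=-60.0)
    assert ev.peak_time == pytest.approx(10.0, abs=1.0 / fs)
    assert ev.onset == pytest.approx(9.9, abs=1.5 / fs)
    assert ev.offset == pytest.approx(11.3, abs=1.5 / fs)
    assert ev.peak_value == pytest.approx(-88.0, abs=2.0)


def test_all_positive_signal_gives_no_kcomplexes():
    x = np.abs(np.random.default_rng(0).standard_normal(2048)) + 1.0
    assert detect_kcomplexes(x, FS, thr=-60.0) == []


def test_refractory_keeps_the_deeper_of_two_close_minima():
    cfg = DetectionConfig(enable_pp_gate=False)
    x = np.zeros(int(20 * FS))

    def dip(t, depth):
        i = int(t * FS)
        x[i - 6:i + 7] -= depth * np.hanning(13)

    dip(10.0, 80.0)
    dip(10.5, 95.0)
    events = detect_kcomplexes(x, FS, thr=-60.0, cfg=cfg)
    assert len(events) == 1
    assert events[0].peak_time == pytest.approx(10.5, abs=2.0 / FS)


def test_peak_to_peak_gate_filters_small_windows():
    x = np.zeros(int(20 * FS))
    i = int(10 * FS)
    x[i - 6:i + 7] -= 80.0 * np.hanning(13)   # pp = 80 < 75? no: 80 >= 75
    assert len(detect_kcomplexes(x, FS, thr=-60.0)) == 1
    x2 = np.zeros(int(20 * FS))
    x2[i - 6:i + 7] -= 70.0 * np.hanning(13)  # deep enough (< -60) but pp < 75
    assert detect_kcomplexes(x2, FS, thr=-60.0) == []
    cfg = DetectionConfig(enable_pp_gate=False)
    assert len(detect_kcomplexes(x2, FS, thr=-60.0, cfg=cfg)) == 1


def test_event_counts_monotone_in_threshold(rng):
    """Spindle count non-increasing in thr; K-complex count non-increasing
    in |thr| (constructed epochs with several events plus noise)."""
    # thresholds swept above the sustained background level: below it, gap
    # merging of noise runs makes counts non-monotonic by construction
    stat = np.abs(rng.standard_normal(int(60 * FS))) * 2.0
    for k in range(6):
        i = int((3 + 9 * k) * FS)
        stat[i:i + int(0.8 * FS)] += rng.uniform(30, 120)
    counts = [len(detect_spindles(np.zeros(len(stat)), FS, thr, statistic=stat))
              for thr in np.geomspace(10, 200, 12)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))

    trans = rng.standard_normal(int(60 * FS)) * 8.0
    for k in range(6):
        i = int((4 + 9 * k) * FS)
        w = make_kcomplex_waveform(FS, rng.uniform(80, 200))
        trans[i:i + len(w)] += w
    kc_counts = [len(detect_kcomplexes(trans, FS, thr))
                 for thr in np.linspace(-20, -120, 12)]
    assert all(a >= b for a, b in zip(kc_counts, kc_counts[1:]))


def test_detected_events_respect_duration_invariants(rng):
    stat = np.abs(rng.standard_normal(int(60 * FS))) * 10.0
    for k in range(5):
        i = int((4 + 10 * k) * FS)
        stat[i:i + int(rng.uniform(0.4, 4.0) * FS)] += 80.0
    events = detect_spindles(np.zeros(len(stat)), FS, 40.0, statistic=stat)
    for ev in events:
        assert ev.duration >= 0.5 - 1e-9
        assert ev.duration <= 3.0 + 1.0 / FS
    # disjoint per type
    for a, b in zip(events, events[1:]):
        assert a.offset <= b.onset + 1e-9


def test_flatline_recording_yields_no_events():
    rec = Recording(samples=np.zeros(int(40 * FS)), fs=FS)
    events = detect_recording(rec, DetectionThresholds(100.0, -60.0))
    assert events == []


def test_detect_recording_scale_equivariance(rng):
    from spindlekit.synth import SynthConfig, simulate_recording
    cfg = SynthConfig(duration=40.0, fs=FS, seed=7,
                      spindle_density=3.0, kcomplex_density=1.5)
    rec, _ = simulate_recording(cfg)
    thr = DetectionThresholds(10.0, -45.0)
    ev1 = detect_recording(rec, thr)
    rec2 = Recording(samples=2.0 * rec.samples, fs=FS)
    thr2 = DetectionThresholds(40.0, -90.0)   # statistic x4, amplitude x2
    ev2 = detect_recording(rec2, thr2)
    assert [(e.event_type, e.onset, e.offset) for e in ev1] == \
           [(e.event_type, e.onset, e.offset) for e in ev2]


def test_bad_thresholds_rejected():
    with pytest.raises(ValueError):
        DetectionThresholds(-5.0, -60.0)
    with pytest.raises(ValueError):
        DetectionThresholds(10.0, 60.0)
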