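"""Recording/epoch data model, EDF round trips, annotation files, corrections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spindlekit.core_io import (
    CorrectionRecord,
    EventAnnotation,
    Recording,
    apply_corrections,
    compute_event_stats,
    read_annotations,
    read_corrections,
    read_edf_channel,
    segment_epochs,
    write_annotations,
    write_corrections,
    write_edf,
)


# ---------------------------------------------------------------------- EDF

def test_edf_round_trip_within_quantization(tmp_path, rng):
    x = rng.standard_normal(15360) * 40.0
    rec = Recording(samples=x, fs=256.0, channel="C3")
    path = tmp_path / "rt.edf"
    write_edf(path, rec)
    back = read_edf_channel(path, "C3")
    assert len(back.samples) == 15360
    assert back.fs == 256.0
    step = 2 * float(np.abs(x).max()) / 65534
    assert np.max(np.abs(back.samples - x)) <= step


def test_edf_unknown_channel_lists_available(tmp_path):
    rec = Recording(samples=np.zeros(256), fs=256.0, channel="C4")
    path = tmp_path / "c4.edf"
    write_edf(path, rec)
    with pytest.raises(ValueError, match="C4"):
        read_edf_channel(path, "C3")


def test_edf_missing_file():
    with pytest.raises(FileNotFoundError):
        read_edf_channel("/nonexistent/file.edf", "C3")


def test_edf_linear_scaling_full_scale_value(tmp_path):
    """Hand-built EDF: physical ±500 µV, digital ±32767, stored 32767 -> 500 µV."""
    def f(s, w):
        return s[:w].ljust(w).encode("ascii")

    header = b"".join([
        f("0", 8), f("X", 80), f("X", 80), f("01.01.01", 8), f("00.00.00", 8),
        f("512", 8), f("", 44), f("1", 8), f("1", 8), f("1", 4),
        f("C3", 16), f("", 80), f("uV", 8), f("-500", 8), f("500", 8),
        f("-32767", 8), f("32767", 8), f("", 80), f("64", 8), f("", 32),
    ])
    data = np.full(64, 32767, dtype="<i2")
    path = tmp_path / "fullscale.edf"
    path.write_bytes(header + data.tobytes())
    rec = read_edf_channel(path, "C3")
    assert rec.samples[0] == pytest.approx(500.0, abs=0.05)


def test_edf_writer_requires_integer_fs(tmp_path):
    rec = Recording(samples=np.zeros(256), fs=100.5)
    with pytest.raises(ValueError, match="integer"):
        write_edf(tmp_path / "x.edf", rec)


# ------------------------------------------------------------------- epochs

def test_segment_epochs_examples():
    rec = Recording(samples=np.zeros(int(600 * 256)), fs=256.0)
    assert len(segment_epochs(rec, 20.0)) == 30
    rec = Recording(samples=np.zeros(int(19 * 256)), fs=256.0)
    assert segment_epochs(rec, 20.0) == []
    rec = Recording(samples=np.zeros(int(50 * 256)), fs=256.0)
    eps = segment_epochs(rec, 20.0)
    assert [(e.first, e.last) for e in eps] == [(0, 5120), (5120, 10240)]


@settings(derandomize=True, max_examples=30, deadline=None)
@given(dur_s=st.floats(min_value=1.0, max_value=300.0),
       epoch_s=st.sampled_from([5.0, 20.0, 30.0]))
def test_segment_epochs_cover_floor_without_overlap(dur_s, epoch_s):
    fs = 64.0
    rec = Recording(samples=np.zeros(max(int(dur_s * fs), 1)), fs=fs)
    eps = segment_epochs(rec, epoch_s)
    n_per = int(round(epoch_s * fs))
    assert len(eps) == len(rec.samples) // n_per
    for a, b in zip(eps, eps[1:]):
        assert a.last == b.first
    for e in eps:
        assert e.last - e.first == n_per


# -------------------------------------------------------------- annotations

def test_annotation_round_trip(tmp_path):
    evs = [EventAnnotation("spindle", 12.30, 13.10, "e1"),
           EventAnnotation("kcomplex", 1.0, 2.4, "e1")]
    path = tmp_path / "a.tsv"
    write_annotations(evs, path)
    assert read_annotations(path) == sorted(evs, key=lambda e: e.onset)


def test_empty_annotation_file_round_trips(tmp_path):
    path = tmp_path / "empty.tsv"
    write_annotations([], path)
    assert read_annotations(path) == []
    assert path.read_text().startswith("# spindlekit-annotations v1")


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.sampled_from(["spindle", "kcomplex"]),
                          st.floats(0.0, 500.0),
                          st.floats(0.001, 10.0)), max_size=20))
def test_annotation_round_trip_property(tmp_path_factory, items):
    evs = [EventAnnotation(t, round(on, 3), round(on, 3) + round(d, 3) + 0.001, "s")
           for t, on, d in items]
    path = tmp_path_factory.mktemp("ann") / "p.tsv"
    write_annotations(evs, path)
    back = read_annotations(path)
    expect = sorted(evs, key=lambda e: (e.onset, e.offset))
    assert len(back) == len(expect)
    for a, b in zip(back, expect):
        assert a.event_type == b.event_type
        assert a.onset == pytest.approx(b.onset, abs=5e-4)
        assert a.offset == pytest.approx(b.offset, abs=5e-4)


def test_malformed_annotation_line_reports_line_number(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("# spindlekit-annotations v1\n"
                    "scorer\tevent_type\tonset_s\toffset_s\n"
                    "e1\tspindle\t5.000\t4.000\n")
    with pytest.raises(ValueError, match=":3"):
        read_annotations(path)


def test_unknown_event_type_rejected(tmp_path):
    path = tmp_path / "bad2.tsv"
    path.write_text("# spindlekit-annotations v1\n"
                    "e1\tarousal\t5.000\t6.000\n")
    with pytest.raises(ValueError, match="arousal"):
        read_annotations(path)


def test_invalid_interval_rejected_at_construction():
    with pytest.raises(ValueError):
        EventAnnotation("spindle", 5.0, 4.0)
    with pytest.raises(ValueError):
        EventAnnotation("spindle", -1.0, 4.0)


# -------------------------------------------------------------- corrections

def _auto():
    return [EventAnnotation("spindle", 10.0 * i, 10.0 * i + 1.0, "auto")
            for i in range(3)]


def test_apply_corrections_add_and_remove():
    corr = [CorrectionRecord("remove", EventAnnotation("spindle", 10.05, 11.04, "c")),
            CorrectionRecord("add", EventAnnotation("kcomplex", 5.0, 6.4, "c"))]
    out = apply_corrections(_auto(), corr)
    assert len(out) == 3
    assert sum(e.event_type == "kcomplex" for e in out) == 1


def test_apply_corrections_empty_is_identity_and_order_insensitive():
    assert apply_corrections(_auto(), []) == sorted(_auto(), key=lambda e: e.onset)
    corr = [CorrectionRecord("add", EventAnnotation("kcomplex", 5.0, 6.4, "c")),
            CorrectionRecord("remove", EventAnnotation("spindle", 0.0, 1.0, "c"))]
    assert apply_corrections(_auto(), corr) == apply_corrections(_auto(), corr[::-1])


def test_apply_corrections_re_adding_is_noop():
    corr = [CorrectionRecord("add", EventAnnotation("kcomplex", 5.0, 6.4, "c"))]
    once = apply_corrections(_auto(), corr)
    assert apply_corrections(once, corr) == once


def test_orphan_remove_raises():
    corr = [CorrectionRecord("remove", EventAnnotation("spindle", 55.0, 56.0, "c"))]
    with pytest.raises(ValueError, match="orphan"):
        apply_corrections(_auto(), corr)


def test_corrections_file_round_trip(tmp_path):
    corr = [CorrectionRecord("add", EventAnnotation("kcomplex", 5.0, 6.4,
                                                    "correction"))]
    path = tmp_path / "c.tsv"
    write_corrections(corr, path)
    assert read_corrections(path) == corr


# -------------------------------------------------------------------- stats

def test_event_stats_density_and_frequency():
    fs = 256.0
    rec = Recording(samples=10.0 * np.sin(2 * np.pi * 13.0 * np.arange(int(360 * fs)) / fs),
                    fs=fs)
    evs = [EventAnnotation("spindle", 30.0 * i, 30.0 * i + 1.0, "t") for i in range(12)]
    st_ = compute_event_stats(evs, rec, "spindle")
    assert st_.total_count == 12
    assert st_.density == pytest.approx(2.0)          # 12 events / 6 min
    assert st_.mean_frequency == pytest.approx(13.0, abs=0.5)
    assert st_.mean_amplitude == pytest.approx(20.0, rel=0.02)
    assert st_.mean_duration == pytest.approx(1.0)


def test_event_stats_no_events():
    rec = Recording(samples=np.zeros(2560), fs=256.0)
    st_ = compute_event_stats([], rec, "spindle")
    assert st_.total_count == 0 and st_.density == 0.0
    assert np.isnan(st_.mean_frequency)
    assert st_.to_dict()["mean_frequency_hz"] is None
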