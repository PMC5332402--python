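"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from spindlekit.calibrate import PreparedPage
from spindlekit.synth import make_kcomplex_waveform, make_spindle_waveform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tone_transient_epoch(rng, fs=128.0, n=512, tone_amp_pp=40.0, kc_amp_pp=100.0):
    """Noise-free epoch with one tone burst and one disjoint biphasic transient.

    Returns (x, tone_slice, transient_slice); positions are drawn at random
    but kept >= 0.5 s apart.
    """
    x = np.zeros(n)
    dur_tone = rng.uniform(0.6, 1.2)
    f_tone = rng.uniform(11.0, 16.0)
    w_tone = make_spindle_waveform(fs, f_tone, dur_tone, tone_amp_pp)
    w_kc = make_kcomplex_waveform(fs, kc_amp_pp)
    total = n / fs
    for _ in range(200):
        t_tone = rng.uniform(0.2, total - dur_tone - 0.2)
        t_kc = rng.uniform(0.2, total - len(w_kc) / fs - 0.2)
        a1, b1 = t_tone, t_tone + dur_tone
        a2, b2 = t_kc, t_kc + len(w_kc) / fs
        if b1 + 0.5 <= a2 or b2 + 0.5 <= a1:
            break
    i1, i2 = int(t_tone * fs), int(t_kc * fs)
    x[i1:i1 + len(w_tone)] += w_tone
    x[i2:i2 + len(w_kc)] += w_kc
    return x, slice(i1, i1 + len(w_tone)), slice(i2, i2 + len(w_kc))


def stub_page(statistic, transient, fs, ref_spindle=None, ref_kc=None, index=0):
    """PreparedPage built from raw arrays (no MCA), for calibration tests."""
    n = len(statistic)
    z = np.zeros(n, dtype=bool)
    return PreparedPage(
        index=index,
        fs=fs,
        oscillatory=np.sqrt(np.maximum(statistic, 0.0)),  # placeholder signal
        transient=np.asarray(transient, dtype=float),
        statistic=np.asarray(statistic, dtype=float),
        ref_labels={
            "spindle": z.copy() if ref_spindle is None else np.asarray(ref_spindle, bool),
            "kcomplex": z.copy() if ref_kc is None else np.asarray(ref_kc, bool),
        },
    )
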