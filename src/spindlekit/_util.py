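"""Small shared signal helpers."""

from __future__ import annotations

import numpy as np

#: Search band (Hz) for an event's dominant frequency.
DOMFREQ_BAND = (5.0, 30.0)


def dominant_frequency(seg: np.ndarray, fs: float,
                       fmin: float = DOMFREQ_BAND[0],
                       fmax: float = DOMFREQ_BAND[1]) -> float:
    """Dominant frequency (Hz) of ``seg``: magnitude-spectrum peak of the
    Hann-windowed segment, searched in ``[fmin, fmax]``.

    The spectrum is zero-padded (8x, next power of two) so the peak location
    is resolved well below the raw DFT bin width even for 0.5-s events.
    Returns NaN for segments too short to resolve the band.
    """
    seg = np.asarray(seg, dtype=float)
    n = len(seg)
    if n < 4:
        return float("nan")
    win = np.hanning(n)
    nfft = int(2 ** np.ceil(np.log2(8 * n)))
    spec = np.abs(np.fft.rfft(seg * win, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    band = (freqs >= fmin) & (freqs <= fmax)
    if not np.any(band):
        return float("nan")
    return float(freqs[band][np.argmax(spec[band])])


def moving_mean_square(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centered moving average of ``x**2`` over a ``window_s`` window."""
    w = max(int(round(window_s * fs)), 1)
    if w % 2 == 0:
        w += 1  # odd length keeps the window centered
    kernel = np.full(w, 1.0 / w)
    return np.convolve(x * x, kernel, mode="same")


def robust_sigma(x: np.ndarray) -> float:
    """Robust scale estimate: median absolute deviation / 0.6745."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))) / 0.6745)
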