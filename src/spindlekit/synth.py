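"""Seeded generator of N2-like sleep EEG with ground-truth events.

Stands in for annotated polysomnography so the full pipeline is testable
without access to a sleep database.  A recording is 1/f-shaped Gaussian
background plus embedded spindles (Hann-enveloped sigma-band sinusoids,
11-16 Hz, 0.5-2 s) and K-complexes (a sharp negative raised-cosine lobe
immediately followed by a slower positive lobe, peak-to-peak >= 75 µV),
placed uniformly at random with at least 1 s separation.  Event parameters
are drawn uniformly from the configured ranges; the ground truth records
each event's extent and parameters.

What this emulates — and what it does not: the background matches the
broadband 1/f character and overall scale of N2 EEG, but contains no true
background sigma rhythms, no slow-oscillation structure, no artifacts
(EMG, eye movements) and no sleep-stage transitions, so detection scores
measured here are an upper bound on what heterogeneous clinical data would
give.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Recording, EventAnnotation

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "make_background",
    "make_spindle_waveform",
    "make_kcomplex_waveform",
    "simulate_recording",
]


@dataclass
class SynthConfig:
    """Generator settings.  Amplitudes in µV peak-to-peak, times in seconds."""

    duration: float = 600.0
    fs: float = 256.0
    seed: int = 0
    spindle_density: float = 3.0        # events per minute
    kcomplex_density: float = 1.2       # events per minute
    spindle_amp_pp: tuple[float, float] = (20.0, 60.0)
    spindle_freq: tuple[float, float] = (11.0, 16.0)
    spindle_dur: tuple[float, float] = (0.5, 2.0)
    kcomplex_amp_pp: tuple[float, float] = (75.0, 200.0)
    background_sd: float = 15.0         # µV
    background_exponent: float = 1.0    # 1/f**gamma spectral slope
    #: noisy-expert emulation (off by default): jitter truth bounds and
    #: drop events at the given miss rate
    expert_jitter_s: float = 0.0
    expert_miss_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.spindle_density < 0 or self.kcomplex_density < 0:
            raise ValueError("event densities must be >= 0")
        for name in ("spindle_amp_pp", "spindle_freq", "spindle_dur", "kcomplex_amp_pp"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is not ordered: ({lo}, {hi})")
        if self.kcomplex_amp_pp[0] < 75.0:
            raise ValueError("K-complex amplitudes must be >= 75 µV peak-to-peak")
        if self.spindle_dur[0] < 0.5:
            raise ValueError("spindle durations must be >= 0.5 s")
        if not (11.0 <= self.spindle_freq[0] and self.spindle_freq[1] <= 16.0):
            raise ValueError("spindle frequencies must lie within 11-16 Hz")


@dataclass
class GroundTruth:
    """True events plus their generating parameters.

    ``events`` are annotations with scorer ``"truth"``; ``params[i]`` holds
    the i-th event's drawn parameters (freq/amp/duration for spindles,
    amp/peak time for K-complexes).
    """

    events: list[EventAnnotation]
    params: list[dict]


def make_background(duration: float, fs: float, sd: float = 15.0,
                    gamma: float = 1.0, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Zero-mean Gaussian noise spectrally shaped to 1/f**gamma, SD = ``sd``.

    ``gamma = 0`` gives white noise.  The output is renormalized so its
    sample standard deviation equals ``sd`` exactly.
    """
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("background needs at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-gamma / 2.0)
    shape[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shape, n)
    x -= x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


def make_spindle_waveform(fs: float, freq: float, dur: float, amp_pp: float) -> np.ndarray:
    """Hann-enveloped sinusoid; peak-to-peak rescaled to exactly ``amp_pp``."""
    if dur < 0.5:
        raise ValueError("spindle duration must be >= 0.5 s")
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    w = np.hanning(n) * np.sin(2.0 * np.pi * freq * t)
    span = w.max() - w.min()
    return w * (amp_pp / span)


#: K-complex template lobe durations (s): sharp negative wave, slower
#: positive rebound; total 1.0 s (within the >= 0.5 s scoring convention).
KC_NEG_LOBE_S = 0.3
KC_POS_LOBE_S = 0.7
#: Fraction of the peak-to-peak amplitude carried by the negative lobe.
KC_NEG_FRACTION = 0.55


def make_kcomplex_waveform(fs: float, amp_pp: float) -> np.ndarray:
    """Biphasic K-complex template, peak-to-peak exactly ``amp_pp``.

    A 0.3-s negative raised-cosine lobe immediately followed by a 0.7-s
    positive lobe; the negative peak precedes the positive one.
    """
    n1 = int(round(KC_NEG_LOBE_S * fs))
    n2 = int(round(KC_POS_LOBE_S * fs))
    neg = -KC_NEG_FRACTION * np.sin(np.pi * np.arange(n1) / n1) ** 2
    pos = (1.0 - KC_NEG_FRACTION) * np.sin(np.pi * np.arange(n2) / n2) ** 2
    w = np.concatenate([neg, pos])
    return w * (amp_pp / (w.max() - w.min()))


def _place_events(rng: np.random.Generator, durations: list[float],
                  total_s: float, margin_s: float = 1.0,
                  max_tries: int = 2000) -> list[float]:
    """Uniform random onsets with >= ``margin_s`` between event intervals."""
    placed: list[tuple[float, float]] = []
    onsets: list[float] = []
    for dur in durations:
        hi = total_s - dur - margin_s
        if hi <= margin_s:
            raise ValueError("recording too short for requested events")
        for _ in range(max_tries):
            onset = rng.uniform(margin_s, hi)
            if all(onset - margin_s >= b or onset + dur + margin_s <= a
                   for a, b in placed):
                placed.append((onset, onset + dur))
                onsets.append(onset)
                break
        else:
            raise ValueError(
                "could not place events disjointly; lower the event densities"
            )
    return onsets


def simulate_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Generate one recording and its ground truth (bit-reproducible by seed).

    Event counts are Poisson with mean density x duration; events are
    placed uniformly at random with >= 1 s margins.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    x = make_background(cfg.duration, cfg.fs, cfg.background_sd,
                        cfg.background_exponent, rng)

    minutes = cfg.duration / 60.0
    n_sp = rng.poisson(cfg.spindle_density * minutes)
    n_kc = rng.poisson(cfg.kcomplex_density * minutes)

    sp_par = [{"event_type": "spindle",
               "freq": rng.uniform(*cfg.spindle_freq),
               "dur": rng.uniform(*cfg.spindle_dur),
               "amp_pp": rng.uniform(*cfg.spindle_amp_pp)} for _ in range(n_sp)]
    kc_par = [{"event_type": "kcomplex",
               "dur": (KC_NEG_LOBE_S + KC_POS_LOBE_S),
               "amp_pp": rng.uniform(*cfg.kcomplex_amp_pp)} for _ in range(n_kc)]
    params = sp_par + kc_par
    onsets = _place_events(rng, [p["dur"] for p in params], cfg.duration)

    events: list[EventAnnotation] = []
    for p, onset in zip(params, onsets):
        if p["event_type"] == "spindle":
            w = make_spindle_waveform(cfg.fs, p["freq"], p["dur"], p["amp_pp"])
        else:
            w = make_kcomplex_waveform(cfg.fs, p["amp_pp"])
        i0 = int(round(onset * cfg.fs))
        x[i0:i0 + len(w)] += w[:max(len(x) - i0, 0)]
        p["onset"] = i0 / cfg.fs
        p["offset"] = (i0 + len(w)) / cfg.fs
        if p["event_type"] == "kcomplex":
            p["peak_time"] = (i0 + int(np.argmin(w))) / cfg.fs
        events.append(EventAnnotation(p["event_type"], p["onset"], p["offset"],
                                      scorer="truth"))

    order = np.argsort([e.onset for e in events])
    events = [events[i] for i in order]
    params = [params[i] for i in order]

    if cfg.expert_jitter_s > 0 or cfg.expert_miss_rate > 0:
        events, params = _noisy_expert(rng, events, params, cfg)

    rec = Recording(samples=x, fs=cfg.fs, channel="C3-synthetic")
    return rec, GroundTruth(events=events, params=params)


def _noisy_expert(rng, events, params, cfg):
    """Jitter boundaries and drop events to emulate an imperfect scorer."""
    kept_e, kept_p = [], []
    for ev, par in zip(events, params):
        if rng.uniform() < cfg.expert_miss_rate:
            continue
        j1 = rng.uniform(-cfg.expert_jitter_s, cfg.expert_jitter_s)
        j2 = rng.uniform(-cfg.expert_jitter_s, cfg.expert_jitter_s)
        onset = max(ev.onset + j1, 0.0)
        offset = max(ev.offset + j2, onset + 0.1)
        kept_e.append(EventAnnotation(ev.event_type, onset, offset, scorer="expert"))
        kept_p.append(par)
    return kept_e, kept_p
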