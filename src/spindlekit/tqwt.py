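"""Tunable Q-factor wavelet transform (TQWT).

An oversampled, perfect-reconstruction discrete wavelet transform whose
Q-factor (ratio of an atom's center frequency to its bandwidth) is a free
design parameter.  High Q yields sustained, narrow-band oscillatory atoms
(suited to sleep spindles); Q near 1 yields brief, wide-band transient atoms
(suited to K-complexes).

The transform is built in the DFT domain as an iterated two-channel filter
bank.  Each level splits the current low-pass signal with a pair of
frequency-domain filters whose squared magnitudes sum to one pointwise
(a power-complementary pair with a raised-cosine-like transition function),
then resamples the two branches by the scaling factors ``alpha`` (low-pass)
and ``beta`` (high-pass).  Because the DFT is used with unitary
normalization and the filters are power complementary, the transform is a
Parseval frame: coefficient energy equals signal energy, and the inverse is
the adjoint.

Scaling factors are derived from the Q-factor ``Q`` and the redundancy
``r``::

    beta  = 2 / (Q + 1)
    alpha = 1 - beta / r
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "TQWTParams",
    "SubbandSet",
    "tqwt_scalars",
    "max_levels",
    "tqwt_forward",
    "tqwt_inverse",
    "center_frequencies",
]


def tqwt_scalars(Q: float, r: float) -> tuple[float, float]:
    """Return the low-/high-pass scaling pair ``(alpha, beta)`` for ``(Q, r)``.

    ``beta = 2/(Q+1)`` and ``alpha = 1 - beta/r``, so that
    ``alpha + beta/r == 1`` exactly.

    Raises
    ------
    ValueError
        If ``Q < 1`` or ``r <= 1``.
    """
    if Q < 1:
        raise ValueError(f"Q-factor must be >= 1, got {Q}")
    if r <= 1:
        raise ValueError(f"redundancy r must be > 1, got {r}")
    beta = 2.0 / (Q + 1.0)
    alpha = 1.0 - beta / r
    return alpha, beta


@dataclass(frozen=True)
class TQWTParams:
    """Parameters of one TQWT dictionary.

    Attributes
    ----------
    Q : float
        Q-factor (>= 1, dimensionless).
    r : float
        Redundancy / oversampling factor (> 1, dimensionless).
    J : int
        Number of high-pass levels (>= 1).  A ``J``-level transform produces
        ``J + 1`` subbands (``J`` wavelet scales plus the low-pass residual).
    """

    Q: float
    r: float
    J: int

    def __post_init__(self) -> None:
        tqwt_scalars(self.Q, self.r)  # validates Q, r
        if int(self.J) != self.J or self.J < 1:
            raise ValueError(f"J must be a positive integer, got {self.J}")

    @property
    def beta(self) -> float:
        return 2.0 / (self.Q + 1.0)

    @property
    def alpha(self) -> float:
        return 1.0 - self.beta / self.r


def max_levels(N: int, Q: float, r: float) -> int:
    """Deepest level count whose filters still fit a length-``N`` signal.

    ``J_max = floor( log(beta*N/8) / log(1/alpha) )``.
    """
    if N < 16:
        raise ValueError(f"signal too short for TQWT (need N >= 16, got {N})")
    alpha, beta = tqwt_scalars(Q, r)
    return int(np.floor(np.log(beta * N / 8.0) / np.log(1.0 / alpha)))


def _even_round(x: float) -> int:
    """Nearest even integer to ``x`` (ties resolved by round-half-even)."""
    return 2 * int(round(x / 2.0))


@lru_cache(maxsize=256)
def _length_chain(N: int, Q: float, r: float, J: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Per-level (input length, high-pass subband length) bookkeeping.

    Returns ``(parents, highs)`` where ``parents[j]`` is the length of the
    signal entering level ``j`` and ``highs[j]`` the length of its high-pass
    subband; the final low-pass has length ``parents[J-1]`` scaled by alpha.
    """
    alpha, beta = tqwt_scalars(Q, r)
    parents, highs = [], []
    Ncur = N
    for _ in range(J):
        N1 = _even_round(beta * Ncur)
        N0 = _even_round(alpha * Ncur)
        if N0 + N1 < Ncur + 2 or N0 < 4 or N1 < 4:
            raise ValueError(
                f"TQWT level lengths degenerate (N={Ncur}, N0={N0}, N1={N1}); reduce J"
            )
        parents.append(Ncur)
        highs.append(N1)
        Ncur = N0
    return tuple(parents), tuple(highs + [Ncur])


def _transition_gains(T: int) -> tuple[np.ndarray, np.ndarray]:
    """Low-/high-pass gains over the ``T`` transition bins.

    Uses the power-complementary transition function
    ``theta(w) = 0.5*(1+cos w)*sqrt(2-cos w)``; the pair satisfies
    ``g0**2 + g1**2 == 1`` pointwise.
    """
    v = np.arange(1, T + 1) * (np.pi / (T + 1))
    g0 = 0.5 * (1.0 + np.cos(v)) * np.sqrt(2.0 - np.cos(v))
    g1 = 0.5 * (1.0 - np.cos(v)) * np.sqrt(2.0 + np.cos(v))  # = theta(pi - v)
    return g0, g1


def _afb(X: np.ndarray, N0: int, N1: int) -> tuple[np.ndarray, np.ndarray]:
    """One analysis split of a unitary DFT ``X`` into low/high spectra."""
    N = len(X)
    P = (N - N1) // 2          # low-pass pass-band bins (each side, excl. DC)
    T = (N0 + N1 - N) // 2 - 1  # transition bins
    g0, g1 = _transition_gains(T)

    V0 = np.zeros(N0, dtype=complex)
    V0[0] = X[0]
    V0[1:P + 1] = X[1:P + 1]
    V0[P + 1:P + T + 1] = g0 * X[P + 1:P + T + 1]
    # V0[N0//2] (its own Nyquist) stays zero
    V0[N0 - P - T:N0 - P] = g0[::-1] * X[N - P - T:N - P]
    if P:
        V0[N0 - P:] = X[N - P:]

    V1 = np.zeros(N1, dtype=complex)
    V1[1:T + 1] = g1 * X[P + 1:P + T + 1]
    V1[T + 1:N1 // 2 + 1] = X[P + T + 1:N // 2 + 1]
    V1[N1 // 2 + 1:N1 - T] = X[N // 2 + 1:N - P - T]
    V1[N1 - T:] = g1[::-1] * X[N - P - T:N - P]
    return V0, V1


def _sfb(V0: np.ndarray, V1: np.ndarray, N: int) -> np.ndarray:
    """Synthesis counterpart of :func:`_afb`; exact inverse on its range."""
    N0, N1 = len(V0), len(V1)
    P = (N - N1) // 2
    T = (N0 + N1 - N) // 2 - 1
    g0, g1 = _transition_gains(T)

    Y = np.zeros(N, dtype=complex)
    Y[0] = V0[0]
    Y[1:P + 1] = V0[1:P + 1]
    Y[P + 1:P + T + 1] = g0 * V0[P + 1:P + T + 1] + g1 * V1[1:T + 1]
    Y[P + T + 1:N // 2 + 1] = V1[T + 1:N1 // 2 + 1]
    Y[N // 2 + 1:N - P - T] = V1[N1 // 2 + 1:N1 - T]
    Y[N - P - T:N - P] = g0[::-1] * V0[N0 - P - T:N0 - P] + g1[::-1] * V1[N1 - T:]
    if P:
        Y[N - P:] = V0[N0 - P:]
    return Y


@dataclass
class SubbandSet:
    """Coefficients of one TQWT analysis.

    ``levels[0] .. levels[J-1]`` are the high-pass (wavelet) subbands from
    finest to coarsest; ``levels[J]`` is the low-pass residual.
    ``n_original`` is the untransformed signal length (before any even-length
    padding).
    """

    levels: list[np.ndarray]
    n_original: int
    params: TQWTParams

    def __post_init__(self) -> None:
        expected = self.expected_lengths()
        got = tuple(len(b) for b in self.levels)
        if got != expected:
            raise ValueError(
                f"inconsistent subband lengths: got {got}, expected {expected}"
            )

    def expected_lengths(self) -> tuple[int, ...]:
        n_pad = self.n_original + (self.n_original % 2)
        _, lengths = _length_chain(n_pad, self.params.Q, self.params.r, self.params.J)
        return lengths

    def energy(self) -> float:
        return float(sum(np.sum(b * b) for b in self.levels))


def tqwt_forward(x: np.ndarray, p: TQWTParams) -> SubbandSet:
    """Analyze ``x`` into ``p.J + 1`` subbands.

    Odd-length inputs are zero-padded to even length; :func:`tqwt_inverse`
    truncates back.  Raises if ``p.J`` exceeds :func:`max_levels` for the
    (padded) signal length.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("tqwt_forward expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    n_orig = len(x)
    if n_orig % 2:
        x = np.concatenate([x, [0.0]])
    N = len(x)
    jmax = max_levels(N, p.Q, p.r)
    if p.J > jmax:
        raise ValueError(f"J={p.J} too deep for N={N}: J_max={jmax}")

    parents, _ = _length_chain(N, p.Q, p.r, p.J)
    X = np.fft.fft(x) / np.sqrt(N)
    subbands: list[np.ndarray] = []
    for Ncur in parents:
        N1 = _even_round(p.beta * Ncur)
        N0 = _even_round(p.alpha * Ncur)
        X, V1 = _afb(X, N0, N1)
        subbands.append((np.fft.ifft(V1) * np.sqrt(N1)).real)
    subbands.append((np.fft.ifft(X) * np.sqrt(len(X))).real)
    return SubbandSet(levels=subbands, n_original=n_orig, params=p)


def tqwt_inverse(w: SubbandSet) -> np.ndarray:
    """Synthesize a signal from its subbands (exact inverse of the forward)."""
    p = w.params
    n_pad = w.n_original + (w.n_original % 2)
    parents, _ = _length_chain(n_pad, p.Q, p.r, p.J)

    low = w.levels[-1]
    X = np.fft.fft(low) / np.sqrt(len(low))
    for j in range(p.J - 1, -1, -1):
        band = w.levels[j]
        V1 = np.fft.fft(band) / np.sqrt(len(band))
        X = _sfb(X, V1, parents[j])
    x = (np.fft.ifft(X) * np.sqrt(n_pad)).real
    return x[:w.n_original]


def center_frequencies(p: TQWTParams, fs: float) -> np.ndarray:
    """Center frequency (Hz) of each of the ``J`` wavelet subbands.

    ``fc(j) = alpha**(j-1) * (2 - beta) * fs / 4`` for ``j = 1..J``; a
    strictly decreasing sequence below ``fs/2``.
    """
    j = np.arange(1, p.J + 1)
    return p.alpha ** (j - 1) * (2.0 - p.beta) * fs / 4.0


def subband_atom_norms(n: int, p: TQWTParams) -> np.ndarray:
    """l2 norm of the synthesis atom of each subband for input length ``n``.

    Computed by inverting a unit coefficient placed at the center of each
    subband.  Because the frame is Parseval these equal the analysis atom
    norms; they are used to equalize soft-threshold levels across scales.
    """
    return np.asarray(_atom_norms_cached(n, p.Q, p.r, p.J))


@lru_cache(maxsize=64)
def _atom_norms_cached(n: int, Q: float, r: float, J: int) -> tuple[float, ...]:
    p = TQWTParams(Q=Q, r=r, J=J)
    n_pad = n + (n % 2)
    _, lengths = _length_chain(n_pad, Q, r, J)
    norms = []
    for j, L in enumerate(lengths):
        levels = [np.zeros(m) for m in lengths]
        levels[j][L // 2] = 1.0
        w = SubbandSet(levels=levels, n_original=n, params=p)
        norms.append(float(np.linalg.norm(tqwt_inverse(w))))
    return tuple(norms)
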