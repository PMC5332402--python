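# Methods

This note documents the models, parameters and numerical choices behind
spindlekit, and what its synthetic benchmarks do and do not establish.

## Tunable-Q wavelet transform (`spindlekit.tqwt`)

The TQWT is an oversampled two-channel filter bank iterated on its low-pass
branch, built radially in the DFT domain. The Q-factor `Q` (atom center
frequency over bandwidth) and redundancy `r` set the scaling factors
`beta = 2/(Q+1)` (high-pass) and `alpha = 1 − beta/r` (low-pass); level `j`
has center frequency `fc(j) = alpha^(j−1) (2−beta) fs/4`. The two filters
overlap only in a transition band shaped by
`theta(w) = ½(1+cos w)√(2−cos w)`, which is power complementary
(`|H0|² + |H1|² = 1` pointwise), so with unitary DFT normalization the
transform is a Parseval frame: analysis conserves energy exactly and the
adjoint is the inverse. Subband lengths are fixed by rounding `alpha·N` and
`beta·N` to even integers (round-half-even); odd-length inputs are
zero-padded by one sample and truncated after inversion. The depth bound is
`J_max = ⌊log(beta·N/8)/log(1/alpha)⌋`. Measured round-trip error on random
signals is at machine precision (~1e−15 relative), against the documented
guarantee of 1e−10.

## Morphological component analysis (`spindlekit.mca`)

An epoch is modeled as oscillatory + transient + residual, obtained from
the dual basis-pursuit denoising objective given in the README. Choices
that matter:

- **Dictionaries** (defaults, overridable): oscillatory `Q=5, r=3,
  J=min(J_max, 40)`; transient `Q=1, r=3, J=min(J_max, 10)`. At 256 Hz the
  high-Q atoms near 13 Hz last ~0.4 s (spindle-like); the low-Q atoms are
  a few tens of milliseconds wide (transient-like).
- **Per-subband weights.** `λ_j = λ · ‖atom_j‖₂` so soft-thresholding bites
  uniformly across scales; global default `λ = 0.8 µV` per dictionary.
- **Low-band penalty.** Both frames represent slow (< 8 Hz) waves cheaply,
  so a K-complex would otherwise split roughly evenly between components.
  Subbands of the oscillatory dictionary centered below 8 Hz, and its
  low-pass residual, carry a ×25 weight penalty, routing slow morphology to
  the transient component. With it, ≥ 97% of a tone burst's energy reaches
  the oscillatory component and ≥ 99% of a biphasic transient's energy the
  transient component on noise-free epochs.
- **Solver.** MFISTA (monotone FISTA): accelerated proximal-gradient steps
  with step size `1/L`, `L = 4` from the frame bound (`ΦΦᵀ = 2I` for the
  two stacked Parseval frames), and a monotone safeguard, so the objective
  trace is non-increasing by construction. We chose it over
  variable-splitting solvers (SALSA/ADMM) because their objective
  oscillates, which would make the documented monotonicity guarantee and
  convergence diagnostics meaningless; routing quality at the same
  iteration budget is identical. Defaults: 100 iterations, early stop when
  an accepted step improves the objective by < 1e−4 relative.
  Non-convergence returns the best iterate with a warning, never an
  exception. The residual is defined by subtraction, so the three
  components sum to the input exactly.
- **Amplitude adaptivity.** In the detection pipeline the global λ is
  rescaled by each epoch's robust SD (MAD/0.6745) relative to a 15 µV
  reference background, making the decomposition — and hence detection,
  with consistently scaled thresholds — equivariant under amplitude
  rescaling of the recording.

## Detection (`spindlekit.detect`)

**Spindles.** Statistic: zero-phase 4th-order Butterworth band-pass of the
oscillatory component to 11–16 Hz (forward–backward, so event timing is
unbiased), squared, then a centered 0.25-s moving average — units µV², a
steady in-band sinusoid of amplitude A maps to A²/2. Detection is
dual-threshold: core runs with statistic > thr for ≥ 0.3 s (gaps < 0.25 s
merged) are extended outward while the statistic stays above 0.1·thr, at
most 0.4 s per side; extended runs < 0.5 s are discarded (AASM minimum) and
runs > 3 s truncated and flagged. The hysteresis stage exists because
spindle tails are spectrally identical to background sigma activity: a
single threshold either misses the tails or floods the record with
background runs, and its sensitivity/precision frontier never reaches
0.8/0.8 on the default synthetic conditions. Count-vs-threshold
monotonicity holds for thresholds above the sustained background level;
within the noise floor, gap merging can make counts locally non-monotone.

**K-complexes.** Local minima of the transient component below the
(negative) threshold, refractory period 1.4 s keeping the deeper peak (ties
to the earlier), each event reported as the standardized window
[peak − 0.1 s, peak + 1.3 s] clipped to the epoch, with a 75 µV
peak-to-peak gate (the expert scoring criterion) on by default. Scoring of
K-complexes is peak-based, so *both* detector and reference events are
mapped to this window before sample-based comparison; the reference peak is
located as the transient-component minimum inside the annotated interval.

Everything runs per 20-s page; epoch-edge events are clipped, not dropped,
so sample-based scoring sees partial windows.

## Threshold calibration (`spindlekit.calibrate`)

Candidate grids: spindles — 50 log-spaced values between the 1% and 99.9%
quantiles of the pooled training statistic; K-complexes — 50 linear values
from the pooled transient minimum to −10 µV. For each candidate the full
detector runs on the training pages and sample-based agreement with the
annotations is pooled. The trained threshold maximizes **sample-based F1**:
with rare events (a few percent positive samples) the Youden index is
nearly flat in the false-positive rate and systematically picks overly
liberal thresholds (PPV 0.4–0.7 on the synthetic conditions);
`optimal_threshold` still defaults to Youden for plain ROC input. Ties
break toward the more sensitive operating point — higher sensitivity
first, then the threshold of smaller magnitude (lower spindle / shallower
K-complex threshold). Note that K-complex thresholds are identifiable only
up to the detection plateau between consecutive peak depths; the tie rule
returns the plateau's most sensitive member.

Variability analyses: the distribution analysis trains on 10 replicate
draws of 30 pages (without replacement, fresh draw per replicate) and
reports quartiles (linear interpolation between order statistics); the
stability analysis draws N ~ uniform{15..120} pages, 60 replicates, bins
the estimates by N into 6 equal-width bins and regresses per-bin mean and
SD on log2(bin center) by OLS (classical t/p from statsmodels; a scorer
indicator is added when several annotation sets are supplied; empty bins
are excluded, single-sample bins excluded from the SD regression).

## Agreement metrics (`spindlekit.metrics`)

Every sample is labeled event/non-event for detector and reference
(half-open intervals, sample k at time k/fs, overlaps unioned); pooled
per-recording confusion counts give sensitivity, PPV, MCC, Cohen's κ and
F1. Zero denominators report 0 and are flagged. Scoring can be restricted
to a caller-supplied epoch subset (e.g. N2-only) by preparing only those
pages.

## Synthetic data (`spindlekit.synth`)

Background: Gaussian noise spectrally shaped to 1/f^γ (γ = 1 default, DC
removed), renormalized to an exact sample SD of 15 µV — the amplitude scale
of central-derivation N2 EEG. Spindles: Hann-enveloped sinusoids, frequency
U[11, 16] Hz, duration U[0.5, 2] s, peak-to-peak U[20, 60] µV (rescaled to
the drawn value exactly). K-complexes: a 0.3-s negative raised-cosine lobe
(55% of the amplitude) immediately followed by a 0.7-s positive lobe,
peak-to-peak U[75, 200] µV. Event counts are Poisson with mean density ×
duration — defaults 3 spindles/min and 1.2 K-complexes/min, central values
for healthy young adults in N2 — and events are placed uniformly at random
with ≥ 1 s margins (bounded retries; over-dense configurations raise). An
optional "noisy expert" mode jitters truth boundaries and drops events to
emulate imperfect human scoring (off by default). Everything is
bit-reproducible from the seed.

What passing tests on this generator show — and what they do not: the
background reproduces the broadband 1/f character and scale of N2 EEG but
contains no genuine background sigma rhythms, slow oscillations, artifacts
or stage transitions, and the event templates are cleaner than real
morphology. Detection scores here are therefore an upper bound on real
recordings; the pipeline's published-scale behavior on clinical data must
be established against expert-scored polysomnography.

## Problem sizes used by the test suite

Chosen so every guarantee is exercised at meaningful scale: morphological
routing — 50 four-second epochs at 128 Hz; threshold recovery — ten 200-s
recordings at 128 Hz; stability analysis — one 40-min recording at 128 Hz
(120 scoring pages, 60 replicates); end-to-end detection — five 5-min
recordings at 256 Hz, each self-calibrated on its own 15 pages. The
end-to-end medians on these conditions are sensitivity/PPV ≈ 0.81/0.91
(spindles) and ≈ 1.00/0.99 (K-complexes).

## Known limitations

- The EDF writer covers the single-channel 16-bit case the pipeline needs
  (integer sampling rates, 1-s records, zero-padded tail); it is not a
  general EDF(+) exporter.
- Threshold units are tied to this pipeline's statistic definitions;
  thresholds from other spindle detectors are not directly comparable.
- MCA runs per 20-s epoch (matching the page-wise scoring workflow);
  events spanning an epoch boundary are detected as clipped fragments.
- The K-complex grid's −10 µV ceiling means very shallow operating points
  ride the grid edge when the peak-to-peak gate already provides the
  precision; this is benign but makes the numeric threshold less
  interpretable there.
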