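# spindlekit

Joint detection of **sleep spindles** and **K-complexes** in single-channel
sleep EEG, for sleep researchers and clinicians who need reproducible,
trainable scoring of N2 micro-events without a GUI.

Spindles (11–16 Hz bursts, ≥ 0.5 s) and K-complexes (a sharp negative wave
immediately followed by a positive component, ≥ 0.5 s, ≥ 75 µV peak-to-peak)
are the defining micro-structures of N2 sleep. Scoring them by eye is slow
and inconsistent, so spindlekit automates the workflow end to end:

1. **Decomposition.** Each 20-s scoring page `x` is split by morphological
   component analysis (MCA) over two tunable-Q wavelet transform (TQWT)
   frames — a high-Q dictionary `Φ₁` whose sustained narrow-band atoms are
   sparse on spindles and a low-Q dictionary `Φ₂` whose brief wide-band
   atoms are sparse on K-complexes — by solving the dual basis-pursuit
   denoising problem

   ```
   min_{w₁,w₂} ‖x − Φ₁w₁ − Φ₂w₂‖₂² + Σⱼ λ₁ⱼ‖w₁ⱼ‖₁ + Σⱼ λ₂ⱼ‖w₂ⱼ‖₁
   ```

   with a monotone FISTA solver. `Φ₁w₁` is the oscillatory component,
   `Φ₂w₂` the transient component.
2. **Detection.** Spindles: sigma-band (11–16 Hz) moving mean-square of the
   oscillatory component (µV²), dual-threshold run detection with the AASM
   ≥ 0.5 s duration rule. K-complexes: negative peaks of the transient
   component below a (negative, µV) threshold, 1.4-s refractory period,
   events reported as the standardized window [peak − 0.1 s, peak + 1.3 s]
   with a 75 µV peak-to-peak gate.
3. **Calibration.** The two thresholds are subject-dependent; they are
   trained from a small visually scored sample (≈ 10 min) by sweeping a
   candidate grid and maximizing sample-based agreement.
4. **Evaluation.** Agreement with reference scoring is computed sample by
   sample: sensitivity, PPV, MCC, Cohen's κ and F1.

A seeded synthetic generator (`spindlekit.synth`) produces N2-like 1/f
background EEG with embedded, ground-truthed spindles and K-complexes so
the whole pipeline can be exercised and tested without access to a
polysomnography database.

## Worked example

Simulate a 5-minute recording, train both thresholds on its scored pages,
detect, and evaluate against the ground truth:

```sh
spindlekit simulate --out-edf night.edf --out-truth truth.tsv \
    --duration 300 --fs 256 --seed 7
spindlekit train night.edf truth.tsv --event-type spindle  --out spindle.json
spindlekit train night.edf truth.tsv --event-type kcomplex --out kcomplex.json
spindlekit detect night.edf --spindle-report spindle.json \
    --kcomplex-report kcomplex.json --out-events auto.tsv --out-stats stats.json
spindlekit eval auto.tsv truth.tsv night.edf --out metrics.json
```

This prints (stderr) `spindle threshold: 11.8`, `kcomplex threshold: -10`,
then `31 events -> auto.tsv`. The exported statistics and metrics read:

```
stats   spindle : total 20, density 4.0 /min, mean duration 1.27 s, mean freq 13.6 Hz
stats   kcomplex: total 11, density 2.2 /min, mean amplitude 163 µV
metrics spindle : sensitivity 0.868  PPV 0.900  MCC 0.873  κ 0.873  F1 0.884
metrics kcomplex: sensitivity 1.000  PPV 0.909  MCC 0.951  κ 0.950  F1 0.952
```

The spindle threshold (11.8 µV² on the smoothed sigma-band power, i.e. an
RMS of about 3.4 µV) and the K-complex threshold are the recording-specific
operating points; densities are events per minute; the metrics are the five
sample-based agreement scores against the generator's ground truth. Manual
thresholds can be supplied instead of reports via `--spindle-thr` /
`--kcomplex-thr`, and false detections can be fixed from a corrections file
with `spindlekit correct`.

The same pipeline is available as a library: `simulate_recording`,
`mca_decompose`, `detect_recording`, `train_threshold`,
`threshold_distribution_analysis`, `threshold_stability_analysis`,
`metric_set`.

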