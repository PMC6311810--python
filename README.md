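# pulsebp

Continuous cuffless blood-pressure estimation from radial-artery pulse
waveforms by **two-domain feature fusion**: six time-domain (morphological)
features and six frequency-domain (spectral) features per five-beat analysis
window feed a small feed-forward network that regresses systolic and
diastolic pressure.

Because no pulse-waveform dataset ships with this package, a synthetic
generator provides physiologically structured records with known ground
truth, so every stage — calibration, conditioning, segmentation,
characteristic-point detection, feature extraction, network training — is
testable end to end without hardware.

## Pipeline

1. **Calibration** (`pulsebp.calibration`) — the sensor's optimal contact
   pressure (OP, newtons) is a cubic function of the subject's BMI:
   `OP(BMI) = −0.0114·BMI³ + 0.7302·BMI² − 15.0889·BMI + 104.4144`,
   valid on BMI ∈ [16, 30]. A stepped pressure-sweep protocol (20 readings
   per 0.5 N force level from 2 to 14 N, running-median baseline, largest
   pulsatile excursion) recovers the OP empirically, and a cross-subject
   cubic fit reproduces the curve.
2. **Conditioning & segmentation** (`pulsebp.preprocess`) — zero-phase
   band-pass 0.15–25 Hz, then beat onsets located at the foot of each
   systolic upstroke via an adaptive threshold on the smoothed derivative.
3. **Characteristic points** (`pulsebp.fiducials`) — per beat: onset (b),
   systolic peak (c), dicrotic notch (d), rebound peak (e) and the optional
   second rebound pair (f, g), with a curvature-based fallback when the
   rebound is submerged.
4. **Features** (`pulsebp.features`) — per 5-beat window:
   time domain `FC, Sss, Sds, Tft, Tst, SL` (peak ratio, systolic/diastolic
   area fractions, notch and upstroke timing ratios, max upstroke slope) and
   frequency domain `A1–A3, P1–P3` (amplitudes and phases of the first three
   cardiac spectral peaks ≥ 0.6 Hz of one FFT over the window).
5. **Fusion & regression** (`pulsebp.fusion_model`) — threshold-matrix
   quality control, mean-shift/unit-variance normalization, and a 12-30-2
   feed-forward network (logistic hidden layer, linear outputs) trained with
   a BFGS quasi-Newton optimizer, 70/15/15 train/validation/test split and
   validation early stopping.

## Command line

```sh
pulsebp simulate record --hr 1.2 --beats 30 --seed 1 --out rec.csv
pulsebp simulate sweep --bmi 22 --out sweep.csv
pulsebp op calc --weight 70 --height 1.75
pulsebp op fit --sweeps sweeps/ --out curve.json
pulsebp preprocess --in rec.csv --out beats.csv
pulsebp fiducials --in rec.csv --out fiducials.csv
pulsebp features --in rec.csv --out features.csv
pulsebp train --features features.csv --labels labels.csv --domains both --out model.json
pulsebp predict --model model.json --features features.csv
pulsebp evaluate --model model.json --features features.csv --labels labels.csv --report report.json
pulsebp pipeline --config cfg.yaml --records records/ --labels labels.csv --out out/
```

Exit codes: 0 success, 2 validation error, 3 data error.

## Benchmark and acceptance metrics

`pulsebp.benchmark` builds seeded synthetic datasets (~1200 windows with
randomized beat morphology and 0.5 mmHg label noise) and compares the fused
12-input model against time-only and frequency-only 6-input ablations.
On these benchmarks the fused model's 95th-percentile absolute test error
stays within ±2 mmHg, the time-only ablation within ±3 mmHg and the
frequency-only ablation within ±9 mmHg, with the ordering
fused ≤ time-only ≤ frequency-only holding across seeded replicates.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
python -m pytest -q tests/
```

The acceptance script reports `t1`/`t2` (first/second characteristic
spectral peak of a canonical noiseless 1.2 Hz record) and `t4`/`t5`/`t6`
(the three ablation error percentiles).

See `docs/methods.md` for the design rationale and algorithmic details.
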