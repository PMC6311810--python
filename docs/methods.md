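# Methods

This note documents the algorithmic choices in pulsebp, the synthetic
ground-truth model, and the rationale for parameters that are not forced by
the problem statement.

## 1. Synthetic pulse-wave model

A beat is the superposition of three Gaussian bumps: the main systolic wave
and two reflected ("rebound") waves delayed by `delay_rebound1` and
`delay_rebound2` seconds from the main peak, with amplitudes expressed as
fractions of the main amplitude. The main peak sits 2.5 kernel widths after
the beat onset so the waveform starts near zero and the upstroke occupies a
realistic 0.1–0.2 s. With the standard parameters (ratios 0.5/0.25, delays
0.22/0.38 s, period 0.83 s) the beat shows three local maxima — the
characteristic points c, e and g — plus the intervening troughs d and f.

Records concatenate beats with per-beat lognormal multiplicative jitter
(default coefficient of variation 2%) on period and amplitudes, add a
sinusoidal respiratory baseline near 0.3 Hz and white Gaussian noise.
All randomness flows from one seeded generator, so records are reproducible
bit for bit. A noiseless record at 1.2 Hz shows spectral lines at 1.2, 2.4
and 4.8 Hz — the cardiac fundamental and its harmonics — plus the 0.3 Hz
respiratory line.

### Ground-truth blood-pressure map

Synthetic labels come from a documented closed form over the generator
parameters (a = main amplitude, r1 = first rebound ratio, d1 = first rebound
delay, T = period):

```
u = 1.5(a−1) + 2.5(r1−0.5) − 10(d1−0.22) − 1.2(T−0.83) + 0.8(a−1)(r1−0.5)
v = 1.0(a−1) + 1.5(r1−0.5) +  5(d1−0.22) − 2.0(T−0.83) + 0.5(r1−0.5)²
DBP = 80 + 14·tanh(v)      PP = 40 + 16·tanh(u)      SBP = DBP + PP
```

The tanh bounds keep every valid parameter set inside a physiological box
(SBP ∈ (90, 150), DBP ∈ (66, 94), pulse pressure ≥ 24 mmHg); the reference
beat maps to exactly 120/80, and SBP is strictly increasing in r1.

The map is deliberately constructed so that *both* feature domains are
informative but neither is sufficient alone:

- The benchmark population varies the systolic width across subjects
  (0.055–0.080 s). The max-slope feature SL scales as amplitude/width, so
  without knowing the width a time-domain model cannot cleanly recover the
  amplitude; the spectral amplitudes A1–A3 resolve that ambiguity.
- The rebound delay d1 carries a strong BP dependence (≈150 mmHg/s near the
  reference point), mirroring the central role of reflected-wave arrival
  time (pulse transit time) in cuffless BP estimation. Time-domain models
  see d1 only through the notch-timing ratio Tft, whose localization noise
  is a few milliseconds; the spectral phases encode d1 through
  onset-invariant phase combinations with much lower noise.

The frequency domain alone, in turn, lacks the precise timing ratios and
area fractions, so each single-domain ablation degrades in its own way and
the fused model wins — which is the behavior the benchmark is designed to
measure.

### Pressure-sweep simulation

For each hold-down force level the film stores 20 readings at 500 ms
intervals. The pulsatile excursion riding on a level follows a Gaussian
response centred on the subject's BMI-derived optimal pressure (width
1.2 N), so the largest |pressure − baseline| excursion appears at the grid
point nearest the true OP.

## 2. Calibration

BMI = weight / height². The optimal contact pressure is the cubic
`OP(BMI) = −0.0114·BMI³ + 0.7302·BMI² − 15.0889·BMI + 104.4144` newtons,
valid on BMI ∈ [16, 30]; above BMI 24 the curve saturates and a warning is
emitted. Sweep analysis: concatenate the per-level samples in level order,
fit a running-median baseline (window 5, end-value replication so the series
keeps its length), take the sample maximizing |pressure − baseline|, and
report its level and baseline value; ties break toward the lower level
(lower contact force is safer). A third-order polynomial fit of OP against
BMI across subjects (computed in a scaled domain for conditioning, then
converted back) recovers the cubic's coefficients exactly from noiseless
samples.

## 3. Conditioning and segmentation

Conditioning is an order-4 Butterworth band-pass, 0.15–25 Hz, applied
forward-backward (zero phase). The band keeps the respiratory line and the
cardiac harmonics, which decay rapidly above ~10 Hz; order 4 was chosen
because order 2 attenuates 50 Hz interference by only ~17×, short of the
targeted ≥ 20×, while order 4 gives > 200× and still passes 1.2 Hz within
5%.

Beat onsets: the smoothed derivative (Gaussian, σ = 15 ms) is thresholded at
40% of its 95th percentile to find systolic upstrokes (minimum spacing
0.3 s); from each maximum-slope point the onset is the sample, walking
backwards, where the derivative falls below 20% of that upstroke's peak
slope. This derivative-threshold foot was preferred over a literal "local
minimum before the upstroke" because the inter-beat foot region of
pulse-like waveforms is nearly flat, making an argmin ill-conditioned under
noise; the walk-back point is stable to within a few milliseconds at noise
up to 2% of the pulse amplitude. Beats are the half-open spans between
consecutive onsets; only periods in [0.3, 2] s are kept, and flat or
aperiodic inputs (autocorrelation < 0.3 across all lags in [0.3, 2] s) raise
a segmentation error.

## 4. Characteristic points and features

Within one beat: b is the onset (index 0), c the global maximum, d the most
prominent local minimum after c, e the first local maximum after d, and
(f, g) the next minimum/maximum pair above a prominence floor of 2% of the
beat height. When no notch exists (submerged rebound), d falls back to the
curvature maximum after c and e is flagged as inferred.

Time features per beat, amplitudes referenced to the onset value:
`FC = h/H` (rebound height over systolic height), `Sss = S1/(S1+S2)` and
`Sds = 1 − Sss` (trapezoidal areas split at the notch), `Tft = (t_d−t_b)/T`,
`Tst = (t_c−t_b)/T`, and `SL` = maximum first-difference slope on the
upstroke. A window's time features are the per-beat features averaged over
its five beats.

Frequency features per window: one FFT over the five concatenated beats
(no zero padding; the long window itself provides the frequency
resolution), one-sided magnitudes normalized by window length. The three
characteristic peaks are the three largest local maxima at ≥ 0.6 Hz —
excluding the respiratory line so A1 is the heart-rate line — ordered by
frequency; Ai is the magnitude and Pi the principal-value phase at each
peak bin. If fewer than three peaks exist, bins at multiples of the
estimated heart rate are used and the result is flagged degenerate.

## 5. Fusion, quality control and the network

The fused vector is (FC, Sss, Sds, Tft, Tst, SL, A1, A2, A3, P1, P2, P3).
A threshold matrix rejects abnormal windows before training (defaults:
period ∈ [0.3, 2] s, ratio features in [0, 1], SL > 0, optionally amplitude
within 5× of the population median); non-finite vectors are rejected under
their own rule, and the rejection report counts per-rule discards.

Inputs and targets are mean-shifted and scaled to unit population standard
deviation (statistics stored in the model). The network is 12-30-2 —
12 inputs, 30 logistic hidden units, 2 linear outputs (SBP, DBP) — trained
by BFGS with analytic gradients on the joint mean-squared error. The hidden
weights use a scaled-uniform seeded init; the output layer starts at zero so
the initial prediction is the target mean. With a validation set, the
validation RMSE is checked every 5 optimizer iterations and training stops
after 6 consecutive non-improving checks (≈ 30 stagnant iterations), keeping
the best-validation weights. Data are split 70/15/15 into
train/validation/test with floor rounding and the remainder to training.

Benchmark experiments train 3 restarts from different seeded inits and keep
the lowest-validation-RMSE model — small MLPs trained by quasi-Newton
methods occasionally stall in poor local minima, and the restart rule is
applied identically to the fused and both single-domain variants so the
comparison stays fair.

Evaluation reports signed errors, a 0.5 mmHg-bin histogram, maximum
absolute error, per-output RMSE and Pearson correlation (flagged NaN when
targets are constant), and the pooled 95th-percentile absolute error used by
the benchmark.

## 6. Benchmark protocol

One record is simulated per analysis window (9 beats; the first complete
beat is skipped against filter edge effects, the next five form the window)
with beat parameters drawn uniformly from documented ranges; windows failing
segmentation or QC are rejected and replaced, with rejection counts kept.
Labels are the closed-form BP of the window's base parameters plus Gaussian
reference-reading noise (sd 0.5 mmHg). The standard benchmark uses ~1200
windows, split 70/15/15. The replicate study repeats dataset generation,
splitting and training across seeds and counts replicates in which
fused ≤ time-only ≤ frequency-only on the pooled p95 absolute error.
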