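"""Synthetic radial-artery pulse-wave generator.

A single beat is modelled as the superposition of a main systolic wave and
two reflected ("rebound") waves arriving with fixed delays, each represented
by a Gaussian bump.  Records concatenate jittered beats, add a sinusoidal
respiratory baseline near 0.3 Hz and white measurement noise, and carry
ground truth (beat onsets, per-beat parameters, reference SBP/DBP) so that
every downstream stage can be validated without hardware recordings.

The generator also simulates the contact-pressure sweep protocol used to
locate the optimal sensor hold-down force: per force level it emits 20
film-pressure readings whose pulsatile excursion peaks at the subject's
BMI-derived optimal pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "BeatParams",
    "RecordSpec",
    "RecordTruth",
    "PulseRecord",
    "simulate_beat",
    "simulate_record",
    "bp_from_params",
    "simulate_pressure_sweep",
    "PEAK_LEAD_WIDTHS",
]

# The main-wave peak sits this many kernel widths after the beat onset, so
# the waveform starts near zero and the upstroke occupies a realistic
# ~0.1-0.2 s.
PEAK_LEAD_WIDTHS = 2.5


@dataclass(frozen=True)
class BeatParams:
    """Morphological parameters of one pulse beat.

    Amplitudes of the two rebound waves are expressed as fractions of the
    main-wave amplitude; delays are measured from the main-wave peak.
    """

    amplitude_main: float = 1.0
    amp_ratio_rebound1: float = 0.5
    amp_ratio_rebound2: float = 0.25
    delay_rebound1: float = 0.22
    delay_rebound2: float = 0.38
    width_main: float = 0.065
    width_r1: float = 0.05
    width_r2: float = 0.05
    period: float = 0.83

    def validate(self) -> None:
        p = self
        if not all(
            math.isfinite(v)
            for v in (
                p.amplitude_main, p.amp_ratio_rebound1, p.amp_ratio_rebound2,
                p.delay_rebound1, p.delay_rebound2,
                p.width_main, p.width_r1, p.width_r2, p.period,
            )
        ):
            raise ParameterError("beat parameters must be finite")
        if p.amplitude_main <= 0:
            raise ParameterError("amplitude_main must be > 0")
        if not (0 <= p.amp_ratio_rebound1 < 1 and 0 <= p.amp_ratio_rebound2 < 1):
            raise ParameterError("rebound amplitude ratios must lie in [0, 1)")
        if p.period <= 0:
            raise ParameterError("period must be > 0")
        if not (0 < p.delay_rebound1 < p.delay_rebound2 < p.period):
            raise ParameterError(
                "delays must satisfy 0 < delay_rebound1 < delay_rebound2 < period"
            )
        for w in (p.width_main, p.width_r1, p.width_r2):
            if not 0 < w < p.period / 2:
                raise ParameterError("kernel widths must lie in (0, period/2)")

    @property
    def t_peak(self) -> float:
        """Time of the main-wave peak relative to the beat onset."""
        return PEAK_LEAD_WIDTHS * self.width_main

    def kernel_centers(self) -> tuple[float, float, float]:
        t0 = self.t_peak
        return (t0, t0 + self.delay_rebound1, t0 + self.delay_rebound2)

    def kernel_amplitudes(self) -> tuple[float, float, float]:
        a = self.amplitude_main
        return (a, a * self.amp_ratio_rebound1, a * self.amp_ratio_rebound2)

    def kernel_widths(self) -> tuple[float, float, float]:
        return (self.width_main, self.width_r1, self.width_r2)


@dataclass(frozen=True)
class RecordSpec:
    """Specification of a synthetic multi-beat record."""

    heart_rate: float = 1.2
    resp_rate: float = 0.3
    resp_amp: float = 0.05
    noise_sd: float = 0.01
    n_beats: int = 30
    fs: float = 500.0
    seed: int = 0
    beat_params: BeatParams = field(default_factory=BeatParams)
    beat_jitter: float = 0.02

    def validate(self) -> None:
        if self.fs < 100:
            raise ParameterError("fs must be at least 100 Hz")
        if not 0.5 <= self.heart_rate <= 3.5:
            raise ParameterError("heart_rate must lie in [0.5, 3.5] Hz")
        if self.resp_rate >= self.heart_rate:
            raise ParameterError("resp_rate must be below heart_rate")
        if self.n_beats < 1:
            raise ParameterError("n_beats must be at least 1")
        if self.noise_sd < 0 or self.resp_amp < 0 or self.beat_jitter < 0:
            raise ParameterError("noise_sd, resp_amp and beat_jitter must be >= 0")
        self.beat_params.validate()


@dataclass
class RecordTruth:
    """Ground truth attached to a synthetic record."""

    sbp: float
    dbp: float
    onsets: np.ndarray  # sample index of each beat onset
    beat_params: list[BeatParams]


@dataclass
class PulseRecord:
    """A sampled pulse waveform with sampling rate and optional ground truth."""

    samples: np.ndarray
    fs: float
    truth: Optional[RecordTruth] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("record samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def simulate_beat(params: BeatParams, fs: float) -> np.ndarray:
    """Return one beat period sampled at ``fs``.

    The beat is the sum of three Gaussian bumps: the main systolic wave
    followed by two rebound waves delayed by ``delay_rebound1`` and
    ``delay_rebound2``.  The waveform starts and ends near zero.
    """
    params.validate()
    if fs <= 0:
        raise ParameterError("fs must be > 0")
    n = int(round(params.period * fs))
    if n < 2:
        raise ParameterError("period too short for sampling rate")
    t = np.arange(n) / fs
    y = np.zeros(n)
    for amp, c, w in zip(
        params.kernel_amplitudes(), params.kernel_centers(), params.kernel_widths()
    ):
        y += amp * _gauss(t, c, w)
    return y


def _jittered(base: BeatParams, factors: np.ndarray) -> BeatParams:
    """Apply multiplicative jitter factors (period, amp, ratio1, ratio2)."""
    return replace(
        base,
        period=base.period * factors[0],
        amplitude_main=base.amplitude_main * factors[1],
        amp_ratio_rebound1=min(base.amp_ratio_rebound1 * factors[2], 0.999),
        amp_ratio_rebound2=min(base.amp_ratio_rebound2 * factors[3], 0.999),
    )


def simulate_record(spec: RecordSpec) -> PulseRecord:
    """Simulate a multi-beat record according to ``spec``.

    Beats are concatenated at the specified heart rate with per-beat
    lognormal multiplicative jitter on period and amplitudes, superposed on
    a sinusoidal respiratory baseline and Gaussian noise.  The output is
    reproducible for a fixed seed; truth carries onset indices, per-beat
    parameters, and the record-level SBP/DBP derived from the base beat
    parameters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = replace(spec.beat_params, period=1.0 / spec.heart_rate)
    base.validate()

    n_samples = int(round(spec.n_beats * spec.fs / spec.heart_rate))
    t = np.arange(n_samples) / spec.fs

    # lognormal multiplicative jitter with coefficient of variation beat_jitter
    if spec.beat_jitter > 0:
        sigma = math.sqrt(math.log(1.0 + spec.beat_jitter**2))
        factors = np.exp(rng.normal(0.0, sigma, size=(spec.n_beats, 4)))
    else:
        factors = np.ones((spec.n_beats, 4))

    beats = [_jittered(base, factors[j]) for j in range(spec.n_beats)]
    onset_times = np.concatenate([[0.0], np.cumsum([b.period for b in beats])[:-1]])

    y = np.zeros(n_samples)
    for onset, bp in zip(onset_times, beats):
        for amp, c, w in zip(bp.kernel_amplitudes(), bp.kernel_centers(), bp.kernel_widths()):
            center = onset + c
            lo = max(0, int((center - 6 * w) * spec.fs))
            hi = min(n_samples, int((center + 6 * w) * spec.fs) + 1)
            if hi > lo:
                y[lo:hi] += amp * _gauss(t[lo:hi], center, w)

    if spec.resp_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        y += (
            spec.resp_amp
            * base.amplitude_main
            * np.sin(2 * np.pi * spec.resp_rate * t + phase)
        )
    if spec.noise_sd > 0:
        y += rng.normal(0.0, spec.noise_sd, size=n_samples)

    onsets = np.round(onset_times * spec.fs).astype(int)
    onsets = onsets[onsets < n_samples]
    sbp, dbp = bp_from_params(base, spec)
    truth = RecordTruth(sbp=sbp, dbp=dbp, onsets=onsets, beat_params=beats)
    return PulseRecord(samples=y, fs=spec.fs, truth=truth)


# --- ground-truth blood-pressure map ---------------------------------------
#
# The map from beat morphology to (SBP, DBP) is a documented closed form:
# two smooth bounded indices
#   u = 1.5 (a - 1) + 2.5 (r1 - 0.5) - 10 (d1 - 0.22) - 1.2 (T - 0.83)
#       + 0.8 (a - 1)(r1 - 0.5)
#   v = 1.0 (a - 1) + 1.5 (r1 - 0.5) + 5 (d1 - 0.22) - 2.0 (T - 0.83)
#       + 0.5 (r1 - 0.5)^2
# with a = amplitude_main, r1 = amp_ratio_rebound1, d1 = delay_rebound1 and
# T = period, drive pulse pressure and diastolic pressure:
#   DBP = 80 + 14 tanh(v),   PP = 40 + 16 tanh(u),   SBP = DBP + PP.
# Hence SBP in (90, 150) mmHg, DBP in (66, 94) mmHg and SBP - DBP >= 24 for
# every valid parameter set; the reference beat maps to exactly 120/80.
# SBP is strictly increasing in amp_ratio_rebound1 for all valid parameters.


def bp_from_params(
    params: BeatParams, spec: Optional[RecordSpec] = None
) -> tuple[float, float]:
    """Deterministic smooth map from beat parameters to (SBP, DBP) in mmHg."""
    params.validate()
    a = params.amplitude_main
    r1 = params.amp_ratio_rebound1
    d1 = params.delay_rebound1
    T = params.period
    u = (
        1.5 * (a - 1.0)
        + 2.5 * (r1 - 0.5)
        - 10.0 * (d1 - 0.22)
        - 1.2 * (T - 0.83)
        + 0.8 * (a - 1.0) * (r1 - 0.5)
    )
    v = (
        1.0 * (a - 1.0)
        + 1.5 * (r1 - 0.5)
        + 5.0 * (d1 - 0.22)
        - 2.0 * (T - 0.83)
        + 0.5 * (r1 - 0.5) ** 2
    )
    dbp = 80.0 + 14.0 * math.tanh(v)
    pp = 40.0 + 16.0 * math.tanh(u)
    return dbp + pp, dbp


# --- contact-pressure sweep --------------------------------------------------

SAMPLES_PER_LEVEL = 20  # film readings stored per force level (500 ms cycles)
SWEEP_SAMPLE_INTERVAL = 0.5  # seconds between film readings


def simulate_pressure_sweep(
    subject,
    levels: Sequence[float],
    seed: int = 0,
    *,
    noise_sd: float = 0.02,
    heart_rate: float = 1.2,
    pulse_gain: float = 0.6,
    response_width: float = 1.2,
) -> pd.DataFrame:
    """Simulate the stepped contact-pressure protocol for one subject.

    For each hold-down force level the film records ``SAMPLES_PER_LEVEL``
    pressure readings at 500 ms intervals.  The pulsatile excursion riding
    on each level follows a Gaussian response centred on the subject's
    optimal pressure (small amplitude when the force is too low, degraded
    again when too high), so the level with the largest excursion marks the
    optimal contact force.

    Returns a DataFrame with columns ``level_N``, ``sample_1..sample_20``
    and ``quality`` (the noise-free pulsatile amplitude at that level).
    """
    from .calibration import optimal_pressure  # local import avoids a cycle

    levels = np.asarray(list(levels), dtype=float)
    if levels.size == 0:
        raise ParameterError("levels must be non-empty")
    if np.any(np.diff(levels) <= 0):
        raise ParameterError("levels must be strictly ascending")
    if levels.min() < 2.0 or levels.max() > 14.0:
        raise ParameterError("levels must lie within [2, 14] N")

    op = subject.op if getattr(subject, "op", None) else optimal_pressure(subject.bmi)
    rng = np.random.default_rng(seed)
    t = np.arange(SAMPLES_PER_LEVEL) * SWEEP_SAMPLE_INTERVAL

    rows = []
    for level in levels:
        quality = pulse_gain * math.exp(-(((level - op) / response_width) ** 2))
        samples = level + quality * np.sin(2 * np.pi * heart_rate * t)
        if noise_sd > 0:
            samples = samples + rng.normal(0.0, noise_sd, size=SAMPLES_PER_LEVEL)
        rows.append([level, *samples, quality])

    columns = (
        ["level_N"]
        + [f"sample_{i}" for i in range(1, SAMPLES_PER_LEVEL + 1)]
        + ["quality"]
    )
    return pd.DataFrame(rows, columns=columns)
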