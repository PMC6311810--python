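"""Time-domain and frequency-domain feature extraction.

Six morphological features are measured per beat, with amplitudes
referenced to the value at the beat onset b:

    FC  = h / H            ratio of rebound-peak to systolic-peak height
    Sss = S1 / (S1 + S2)   systolic fraction of the beat area (b..d)
    Sds = S2 / (S1 + S2)   diastolic fraction (d..end)
    Tft = Tf / T           systole duration b..d over the beat period
    Tst = T1 / T           upstroke duration b..c over the beat period
    SL                     maximum slope on the upstroke b..c

Six spectral features are measured per analysis window of five complete
pulsation cycles: the amplitudes A1-A3 and phases P1-P3 of the first three
characteristic peaks of the FFT magnitude spectrum.  The characteristic
peaks are searched at >= 0.6 Hz so that A1 is the heart-rate line rather
than the ~0.3 Hz respiratory line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import FeatureError, WindowError
from .fiducials import FiducialSet, detect_fiducials
from .preprocess import Beat

__all__ = [
    "TimeFeatures",
    "FreqFeatures",
    "WindowFeatures",
    "extract_time_features",
    "extract_freq_features",
    "build_windows",
    "FEATURE_NAMES",
    "TIME_FEATURE_NAMES",
    "FREQ_FEATURE_NAMES",
    "BEATS_PER_WINDOW",
    "MIN_CARDIAC_HZ",
]

TIME_FEATURE_NAMES = ("FC", "Sss", "Sds", "Tft", "Tst", "SL")
FREQ_FEATURE_NAMES = ("A1", "A2", "A3", "P1", "P2", "P3")
FEATURE_NAMES = TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES

BEATS_PER_WINDOW = 5
MIN_CARDIAC_HZ = 0.6  # excludes the respiratory line from peak search


@dataclass
class TimeFeatures:
    FC: float
    Sss: float
    Sds: float
    Tft: float
    Tst: float
    SL: float

    def as_array(self) -> np.ndarray:
        return np.array([self.FC, self.Sss, self.Sds, self.Tft, self.Tst, self.SL])


@dataclass
class FreqFeatures:
    A1: float
    A2: float
    A3: float
    P1: float
    P2: float
    P3: float
    peak_freqs: tuple[float, float, float]
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.A3, self.P1, self.P2, self.P3])


def extract_time_features(beat: Beat, fid: FiducialSet) -> TimeFeatures:
    """Compute the six morphological features of one beat."""
    y = beat.samples
    fs = beat.fs
    if fid.c <= fid.b:
        raise FeatureError("systolic peak coincides with onset")
    y0 = y[fid.b]
    H = y[fid.c] - y0
    if H <= 0:
        raise FeatureError("non-positive systolic height")
    h = y[fid.e] - y0
    # trapezoidal areas relative to the onset baseline, split at the notch
    s1 = np.trapezoid(y[fid.b : fid.d + 1] - y0) / fs
    s2 = np.trapezoid(y[fid.d :] - y0) / fs
    total = s1 + s2
    if total == 0:
        raise FeatureError("degenerate beat: zero area")
    T = beat.period
    t1 = (fid.c - fid.b) / fs
    tf = (fid.d - fid.b) / fs
    sl = float(np.max(np.diff(y[fid.b : fid.c + 1])) * fs)
    sss = float(s1 / total)
    return TimeFeatures(
        FC=float(h / H),
        Sss=sss,
        Sds=1.0 - sss,  # complement computed exactly
        Tft=float(tf / T),
        Tst=float(t1 / T),
        SL=sl,
    )


def _principal(phase: float) -> float:
    """Map a phase to the half-open interval (-pi, pi]."""
    p = float((phase + np.pi) % (2 * np.pi) - np.pi)
    return np.pi if p == -np.pi else p


def extract_freq_features(
    window, fs: float, n_beats: int = BEATS_PER_WINDOW
) -> FreqFeatures:
    """Spectral features of a window spanning ``n_beats`` complete beats.

    The one-sided magnitude spectrum (normalized by window length) is
    searched for local maxima at >= 0.6 Hz; the three largest, ordered by
    frequency, are the characteristic peaks.  If fewer than three peaks
    exist the features are filled at multiples of the estimated heart rate
    and the result is flagged degenerate.
    """
    x = np.asarray(window, dtype=float)
    n = len(x)
    est_period = n / (n_beats * fs)
    if not 0.3 <= est_period <= 2.0:
        raise WindowError(
            f"window of {n} samples does not span {n_beats} plausible beats"
        )
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mag = np.abs(spec) * 2.0 / n

    start = int(np.searchsorted(freqs, MIN_CARDIAC_HZ))
    candidates, _ = sps.find_peaks(mag[start:])
    candidates = candidates + start
    degenerate = len(candidates) < 3
    if degenerate:
        f0 = 1.0 / est_period
        bins = [int(round(k * f0 * n / fs)) for k in (1, 2, 3)]
        bins = [min(max(b, 1), len(mag) - 1) for b in bins]
    else:
        top3 = candidates[np.argsort(mag[candidates])[-3:]]
        bins = sorted(int(b) for b in top3)

    amps = [float(mag[b]) for b in bins]
    phases = [_principal(np.angle(spec[b])) for b in bins]
    return FreqFeatures(
        A1=amps[0], A2=amps[1], A3=amps[2],
        P1=phases[0], P2=phases[1], P3=phases[2],
        peak_freqs=tuple(float(freqs[b]) for b in bins),
        degenerate=degenerate,
    )


@dataclass
class WindowFeatures:
    """Fused descriptor of one five-beat analysis window.

    Time features are averaged across the window's beats so that both
    domains describe the same span; ``period`` and ``amplitude`` carry the
    raw mean beat period (s) and systolic height for quality control.
    """

    time: TimeFeatures
    freq: FreqFeatures
    period: float
    amplitude: float
    first_onset: int

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.time.as_array(), self.freq.as_array()])


def build_windows(
    beats: list[Beat],
    fs: float,
    beats_per_window: int = BEATS_PER_WINDOW,
    skip_first: int = 0,
) -> list[WindowFeatures]:
    """Group consecutive beats into non-overlapping feature windows.

    Each window concatenates ``beats_per_window`` beats; its time features
    are the per-beat features averaged over the window and its frequency
    features come from one FFT of the concatenated span.  ``skip_first``
    drops leading beats (useful to avoid filter edge effects).
    """
    usable = beats[skip_first:]
    if len(usable) < beats_per_window:
        raise WindowError(
            f"need at least {beats_per_window} beats, got {len(usable)}"
        )
    windows = []
    for i in range(0, len(usable) - beats_per_window + 1, beats_per_window):
        group = usable[i : i + beats_per_window]
        tf_list, heights = [], []
        for beat in group:
            fid = detect_fiducials(beat)
            tf_list.append(extract_time_features(beat, fid).as_array())
            heights.append(beat.samples[fid.c] - beat.samples[fid.b])
        mean_tf = np.mean(tf_list, axis=0)
        samples = np.concatenate([b.samples for b in group])
        freq = extract_freq_features(samples, fs, n_beats=beats_per_window)
        windows.append(
            WindowFeatures(
                time=TimeFeatures(*mean_tf),
                freq=freq,
                period=float(np.mean([b.period for b in group])),
                amplitude=float(np.mean(heights)),
                first_onset=group[0].onset_index,
            )
        )
    return windows
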