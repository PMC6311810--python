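"""Signal conditioning and beat segmentation.

Raw sensor output is band-pass filtered to the 0.15-25 Hz band: this keeps
the ~0.3 Hz respiratory line and the cardiac harmonics (which decay rapidly
above ~10 Hz) while removing drift and high-frequency noise.  The
conditioned signal is then cut into individual pulsation periods at the
foot of each systolic upstroke, so that all morphological features are
measured within a single beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .errors import ParameterError, SegmentationError

__all__ = ["Beat", "condition_signal", "segment_beats", "BAND_HZ"]

BAND_HZ = (0.15, 25.0)  # pass band of the conditioning filter
FILTER_ORDER = 4

MIN_PERIOD_S = 0.3  # accepted beat period range
MAX_PERIOD_S = 2.0

# onset detection tuning
_DERIV_SMOOTH_S = 0.015   # Gaussian smoothing of the derivative
_UPSTROKE_FRACTION = 0.4  # threshold as a fraction of the 95th derivative pct
_FOOT_FRACTION = 0.2      # foot = derivative falls below this x upstroke max
_MIN_AUTOCORR = 0.3       # periodicity acceptance floor


@dataclass
class Beat:
    """One pulsation period cut from a conditioned record."""

    samples: np.ndarray
    fs: float
    onset_index: int
    period: float  # seconds

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("beat samples must be finite")


def condition_signal(raw, fs: float):
    """Zero-phase band-pass (0.15-25 Hz) conditioning of a raw record.

    Output length equals input length; DC and out-of-band noise are
    removed.  Requires at least 2 s of data for the filter edges.
    """
    x = np.asarray(raw, dtype=float)
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if len(x) < 2 * fs:
        raise ParameterError("need at least 2 s of signal for conditioning")
    sos = sps.butter(FILTER_ORDER, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _check_periodicity(x: np.ndarray, fs: float) -> None:
    """Reject flat or aperiodic signals via the autocorrelation."""
    x = x - x.mean()
    power = float(np.dot(x, x))
    if power <= 0 or np.std(x) < 1e-12:
        raise SegmentationError("signal is flat")
    n = len(x)
    spec = np.fft.rfft(x, 2 * n)
    acf = np.fft.irfft(spec * np.conj(spec))[:n] / power
    lo = int(MIN_PERIOD_S * fs)
    hi = min(int(MAX_PERIOD_S * fs) + 1, n)
    if lo >= hi or float(np.max(acf[lo:hi])) < _MIN_AUTOCORR:
        raise SegmentationError("no pulsatile periodicity detected")


def segment_beats(x, fs: float) -> list[Beat]:
    """Segment a conditioned signal into beats at the upstroke feet.

    Upstrokes are found by an adaptive threshold on the smoothed
    derivative; each beat onset is the point, walking back from the
    maximum-slope sample, where the derivative drops below a small fraction
    of that upstroke's peak slope.  Beats are the half-open spans between
    consecutive onsets; the incomplete trailing beat is discarded and only
    periods in [0.3, 2] s are accepted.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < int(2 * MIN_PERIOD_S * fs):
        raise SegmentationError("signal too short to contain two beats")
    _check_periodicity(x, fs)

    deriv = gaussian_filter1d(np.gradient(x) * fs, sigma=_DERIV_SMOOTH_S * fs)
    positive = np.clip(deriv, 0, None)
    thr = _UPSTROKE_FRACTION * np.percentile(positive, 95)
    if thr <= 0:
        raise SegmentationError("no upstrokes found")
    peaks, _ = sps.find_peaks(deriv, height=thr, distance=max(1, int(MIN_PERIOD_S * fs)))
    if len(peaks) < 2:
        raise SegmentationError("fewer than two upstrokes found")

    onsets = []
    back_limit = int(0.35 * fs)
    for p in peaks:
        floor = _FOOT_FRACTION * deriv[p]
        i = p
        while i > max(0, p - back_limit) and deriv[i - 1] > floor:
            i -= 1
        onsets.append(i)
    onsets = np.unique(onsets)

    beats = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        period = (b - a) / fs
        if MIN_PERIOD_S <= period <= MAX_PERIOD_S:
            beats.append(Beat(samples=x[a:b], fs=fs, onset_index=int(a), period=period))
    if not beats:
        raise SegmentationError("no beats with plausible period found")
    return beats
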