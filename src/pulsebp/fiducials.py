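"""Detection of the characteristic points b-g within one beat.

The points are, in order: beat onset (b), main systolic peak (c), the
trough / dicrotic notch after it (d), the first rebound peak (e), and the
optional trough/peak pair (f, g) produced by the second rebound wave.  In
subjects with elastic vessels the rebound waves can be submerged in the
main wave; the detector then falls back to the curvature maximum after the
systolic peak for d and flags e as inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .errors import FiducialError
from .preprocess import Beat

__all__ = ["FiducialSet", "detect_fiducials", "PROMINENCE_FLOOR"]

PROMINENCE_FLOOR = 0.02  # fraction of main-peak height for optional points


@dataclass
class FiducialSet:
    """Sample indices (beat-relative) of the characteristic points."""

    b: int
    c: int
    d: int
    e: int
    f: Optional[int] = None
    g: Optional[int] = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.b < self.c < self.d <= self.e):
            raise FiducialError(
                f"fiducial ordering violated: b={self.b} c={self.c} d={self.d} e={self.e}"
            )
        if self.f is not None and self.g is not None and not self.f < self.g:
            raise FiducialError("f must precede g")


def detect_fiducials(beat: Beat) -> FiducialSet:
    """Locate points b-g in an accepted beat.

    b is the beat onset (index 0); c the global maximum; d the most
    prominent local minimum after c; e the first local maximum after d.
    f and g are the next minimum/maximum pair above the prominence floor,
    else flagged absent.  When no notch exists (submerged rebound), d is
    placed at the maximum of the second derivative after c and e is
    flagged as inferred (e = d).
    """
    y = beat.samples
    n = len(y)
    if n < 4:
        raise FiducialError("beat too short")
    b = 0
    c = int(np.argmax(y))
    if c <= 0 or c >= n - 1:
        raise FiducialError("beat has no interior maximum")
    height = y[c] - y[b]
    prom = PROMINENCE_FLOOR * max(height, np.ptp(y))
    flags: dict = {}

    after = y[c:]
    minima, min_props = sps.find_peaks(-after, prominence=prom)
    if len(minima):
        d = c + int(minima[np.argmax(min_props["prominences"])])
        maxima, _ = sps.find_peaks(y[d:], prominence=prom)
        if len(maxima):
            e = d + int(maxima[0])
        else:
            e = d
            flags["e_inferred"] = True
    else:
        # submerged notch: curvature maximum after the systolic peak
        smooth = gaussian_filter1d(y, sigma=max(1.0, 0.01 * beat.fs))
        curv = np.gradient(np.gradient(smooth))
        if n - 2 <= c + 1:
            raise FiducialError("no room after systolic peak")
        d = c + 1 + int(np.argmax(curv[c + 1 : n - 1]))
        e = d
        flags["d_inferred"] = True
        flags["e_inferred"] = True

    f = g = None
    if e > d:
        minima2, _ = sps.find_peaks(-y[e:], prominence=prom)
        if len(minima2):
            f_cand = e + int(minima2[0])
            maxima2, _ = sps.find_peaks(y[f_cand:], prominence=prom)
            if len(maxima2):
                f = f_cand
                g = f_cand + int(maxima2[0])
    if f is None:
        flags["f_absent"] = True
    if g is None:
        flags["g_absent"] = True

    return FiducialSet(b=b, c=c, d=d, e=e, f=f, g=g, flags=flags)
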