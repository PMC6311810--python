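"""Exception hierarchy shared across the pipeline.

Two families matter for the CLI exit codes: validation problems (bad
parameters, out-of-range configuration) and data problems (signals that
cannot be segmented, files that cannot be parsed).
"""


class PulseBPError(Exception):
    """Base class for all package errors."""


class ParameterError(PulseBPError, ValueError):
    """Invalid argument or configuration value."""


class RangeError(ParameterError):
    """Value outside a documented validity range."""


class DataError(PulseBPError):
    """Input data cannot be processed."""


class ParseError(DataError):
    """A file does not conform to the documented dialect."""


class SegmentationError(DataError):
    """No pulsatile periodicity could be found in a signal."""


class FiducialError(DataError):
    """Characteristic points could not be located in a beat."""


class FeatureError(DataError):
    """A beat is too degenerate for feature extraction."""


class WindowError(DataError):
    """An analysis window does not span the required number of beats."""


class TrainingError(PulseBPError):
    """Network training failed (non-finite loss or gradient)."""


class PredictionRefused(PulseBPError):
    """Prediction requested on a vector that failed quality control."""
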