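"""Two-domain fusion and the blood-pressure regression network.

The six time-domain and six frequency-domain features are concatenated at
the input level into a 12-element vector.  Vectors pass a threshold-matrix
quality check, are mean-shifted and scaled to unit variance, and feed a
feed-forward network with one hidden layer of 30 logistic units and two
linear outputs (SBP, DBP).  Training minimizes the joint mean-squared
error with a BFGS quasi-Newton optimizer and stops early when the
validation error stops improving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import ParameterError, PredictionRefused, TrainingError
from .features import FEATURE_NAMES, WindowFeatures

__all__ = [
    "FeatureVector",
    "ThresholdMatrix",
    "NormStats",
    "TrainConfig",
    "BPModel",
    "EvaluationReport",
    "qc_filter",
    "normalize_fit",
    "normalize_apply",
    "denormalize",
    "split_data",
    "train_ann",
    "predict",
    "evaluate",
]

DEFAULT_HIDDEN = 30
HIST_BIN_MMHG = 0.5
PLAUSIBLE_BP = (40.0, 250.0)


@dataclass
class FeatureVector:
    """The fused 12-element descriptor of one analysis window."""

    values: np.ndarray  # ordered as FEATURE_NAMES
    window_id: int = 0
    qc_pass: bool = True
    raw: dict = field(default_factory=dict)  # e.g. period, amplitude

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ParameterError(
                f"feature vector must have exactly {len(FEATURE_NAMES)} entries"
            )

    @classmethod
    def from_window(cls, wf: WindowFeatures, window_id: int = 0) -> "FeatureVector":
        return cls(
            values=wf.as_array(),
            window_id=window_id,
            raw={"period": wf.period, "amplitude": wf.amplitude},
        )


@dataclass
class ThresholdMatrix:
    """Per-quantity acceptance bounds for abnormal-data rejection."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ParameterError(f"threshold row {name}: lower must be < upper")

    @classmethod
    def default(cls, amplitude_median: Optional[float] = None) -> "ThresholdMatrix":
        bounds = {
            "period": (0.3, 2.0),
            "FC": (0.0, 1.0),
            "Sss": (0.0, 1.0),
            "Sds": (0.0, 1.0),
            "Tft": (0.0, 1.0),
            "Tst": (0.0, 1.0),
            "SL": (0.0, np.inf),
        }
        if amplitude_median is not None:
            bounds["amplitude"] = (amplitude_median / 5.0, 5.0 * amplitude_median)
        return cls(bounds=bounds)


def qc_filter(
    vectors: Sequence[FeatureVector], tm: ThresholdMatrix
) -> tuple[list[FeatureVector], dict[str, int]]:
    """Reject vectors with any monitored quantity outside its bounds.

    Returns the accepted vectors (with ``qc_pass`` set) and a per-rule
    rejection count.  Non-finite features are rejected under the rule
    ``"finite"``.
    """
    name_to_col = {name: i for i, name in enumerate(FEATURE_NAMES)}
    accepted: list[FeatureVector] = []
    report: dict[str, int] = {}
    for vec in vectors:
        reason = None
        if not np.all(np.isfinite(vec.values)):
            reason = "finite"
        else:
            for name, (lo, hi) in tm.bounds.items():
                if name in name_to_col:
                    value = vec.values[name_to_col[name]]
                elif name in vec.raw:
                    value = vec.raw[name]
                else:
                    continue
                if not lo <= value <= hi:
                    reason = name
                    break
        if reason is None:
            vec.qc_pass = True
            accepted.append(vec)
        else:
            vec.qc_pass = False
            report[reason] = report.get(reason, 0) + 1
    return accepted, report


@dataclass
class NormStats:
    """Column means and scales of the training features."""

    mean: np.ndarray
    scale: np.ndarray
    constant_columns: np.ndarray  # boolean flags


def normalize_fit(X: np.ndarray) -> tuple[np.ndarray, NormStats]:
    """Mean-shift and scale columns to unit population standard deviation.

    Zero-variance columns are flagged and left at scale 1 with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError("normalization needs a matrix with at least 2 rows")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)  # population (n) convention
    constant = scale == 0
    if np.any(constant):
        warnings.warn("zero-variance feature column(s); scale set to 1", stacklevel=2)
        scale = np.where(constant, 1.0, scale)
    stats = NormStats(mean=mean, scale=scale, constant_columns=constant)
    return (X - mean) / scale, stats


def normalize_apply(X: np.ndarray, stats: NormStats) -> np.ndarray:
    return (np.asarray(X, dtype=float) - stats.mean) / stats.scale


def denormalize(Xn: np.ndarray, stats: NormStats) -> np.ndarray:
    return np.asarray(Xn, dtype=float) * stats.scale + stats.mean


@dataclass
class Split:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def split_data(
    n_or_X,
    y=None,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> Split:
    """Random disjoint train/validation/test index partition.

    Validation and test sizes are floor-rounded; the remainder goes to
    training.  Reproducible for a fixed seed.
    """
    n = n_or_X if np.isscalar(n_or_X) else len(n_or_X)
    if y is not None and len(y) != n:
        raise ParameterError("X and y lengths differ")
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ParameterError("fractions must be three non-negatives summing to 1")
    if n < 10:
        raise ParameterError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    return Split(
        train=np.sort(perm[:n_train]),
        validation=np.sort(perm[n_train : n_train + n_val]),
        test=np.sort(perm[n_train + n_val :]),
    )


# --- network ----------------------------------------------------------------


@dataclass
class TrainConfig:
    hidden: int = DEFAULT_HIDDEN
    seed: int = 0
    max_iter: int = 1000
    patience: int = 6        # consecutive non-improving validation checks
    val_check_every: int = 5  # optimizer iterations between validation checks
    gtol: float = 1e-8


@dataclass
class TrainLog:
    iterations: int = 0
    train_trace: list = field(default_factory=list)  # normalized MSE per check
    val_trace: list = field(default_factory=list)    # validation RMSE (mmHg)
    stopped_early: bool = False


@dataclass
class BPModel:
    """Trained feed-forward network with its normalization statistics."""

    w1: np.ndarray  # (n_in, hidden)
    b1: np.ndarray
    w2: np.ndarray  # (hidden, 2)
    b2: np.ndarray
    x_stats: NormStats
    y_stats: NormStats
    architecture: tuple[int, int, int]
    config: TrainConfig
    log: TrainLog

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Predict (SBP, DBP) in mmHg for raw (unnormalized) feature rows."""
        Xn = normalize_apply(np.atleast_2d(X), self.x_stats)
        h = _sigmoid(Xn @ self.w1 + self.b1)
        out = h @ self.w2 + self.b2
        return denormalize(out, self.y_stats)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(theta: np.ndarray, n_in: int, hidden: int, n_out: int):
    i = 0
    w1 = theta[i : i + n_in * hidden].reshape(n_in, hidden); i += n_in * hidden
    b1 = theta[i : i + hidden]; i += hidden
    w2 = theta[i : i + hidden * n_out].reshape(hidden, n_out); i += hidden * n_out
    b2 = theta[i : i + n_out]
    return w1, b1, w2, b2


def _loss_grad(theta, Xn, Yn, n_in, hidden, n_out):
    w1, b1, w2, b2 = _unpack(theta, n_in, hidden, n_out)
    h = _sigmoid(Xn @ w1 + b1)
    out = h @ w2 + b2
    err = out - Yn
    n = Xn.shape[0]
    loss = float(np.mean(err**2))
    d_out = 2.0 * err / (n * n_out)
    g_w2 = h.T @ d_out
    g_b2 = d_out.sum(axis=0)
    d_h = (d_out @ w2.T) * h * (1.0 - h)
    g_w1 = Xn.T @ d_h
    g_b1 = d_h.sum(axis=0)
    return loss, _pack(g_w1, g_b1, g_w2, g_b2)


def train_ann(
    train: tuple[np.ndarray, np.ndarray],
    validation: Optional[tuple[np.ndarray, np.ndarray]] = None,
    config: Optional[TrainConfig] = None,
) -> BPModel:
    """Train the feed-forward network on (features, BP-label) pairs.

    Inputs and targets are mean-shifted and scaled internally (statistics
    are stored in the model for prediction).  The hidden layer uses
    logistic units, the output layer is linear, and the joint SBP/DBP
    mean-squared error is minimized by BFGS.  When a validation set is
    given, training keeps the weights with the lowest validation RMSE and
    stops after ``patience`` consecutive checks without improvement.
    """
    config = config or TrainConfig()
    X, Y = (np.asarray(a, dtype=float) for a in train)
    if X.ndim != 2 or Y.ndim != 2 or Y.shape[1] != 2:
        raise ParameterError("train data must be (n, p) features and (n, 2) targets")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise TrainingError("non-finite training data")
    n_in, n_out, hidden = X.shape[1], 2, config.hidden

    Xn, x_stats = normalize_fit(X)
    Yn, y_stats = normalize_fit(Y)

    rng = np.random.default_rng(config.seed)
    limit = np.sqrt(6.0 / (n_in + hidden))
    w1 = rng.uniform(-limit, limit, size=(n_in, hidden))
    b1 = np.zeros(hidden)
    w2 = np.zeros((hidden, n_out))  # zero output layer: initial prediction
    b2 = np.zeros(n_out)            # is the target mean
    theta0 = _pack(w1, b1, w2, b2)

    if validation is not None:
        Xv, Yv = (np.asarray(a, dtype=float) for a in validation)
        Xvn = normalize_apply(Xv, x_stats)
    log = TrainLog()
    best = {"theta": theta0.copy(), "val": np.inf}
    stall = {"count": 0}

    def val_rmse(theta) -> float:
        w1_, b1_, w2_, b2_ = _unpack(theta, n_in, hidden, n_out)
        pred = denormalize(_sigmoid(Xvn @ w1_ + b1_) @ w2_ + b2_, y_stats)
        return float(np.sqrt(np.mean((pred - Yv) ** 2)))

    def callback(theta):
        log.iterations += 1
        if validation is not None and log.iterations % config.val_check_every == 0:
            loss, _ = _loss_grad(theta, Xn, Yn, n_in, hidden, n_out)
            log.train_trace.append(loss)
            v = val_rmse(theta)
            log.val_trace.append(v)
            if v < best["val"]:
                best["val"] = v
                best["theta"] = theta.copy()
                stall["count"] = 0
            else:
                stall["count"] += 1
                if stall["count"] >= config.patience:
                    log.stopped_early = True
                    raise StopIteration

    res = minimize(
        _loss_grad,
        theta0,
        args=(Xn, Yn, n_in, hidden, n_out),
        jac=True,
        method="BFGS",
        callback=callback,
        options={"maxiter": config.max_iter, "gtol": config.gtol},
    )
    if not np.all(np.isfinite(res.x)):
        raise TrainingError("optimizer returned non-finite weights")
    theta = best["theta"] if (validation is not None and np.isfinite(best["val"])) else res.x
    if validation is not None and val_rmse(res.x) < best["val"]:
        theta = res.x
    w1, b1, w2, b2 = _unpack(theta, n_in, hidden, n_out)
    return BPModel(
        w1=w1, b1=b1, w2=w2, b2=b2,
        x_stats=x_stats, y_stats=y_stats,
        architecture=(n_in, hidden, n_out),
        config=config, log=log,
    )


def predict(model: BPModel, vector) -> tuple[float, float]:
    """Predict (SBP, DBP) in mmHg for one feature vector."""
    if isinstance(vector, FeatureVector):
        if not vector.qc_pass:
            raise PredictionRefused("vector failed quality control")
        values = vector.values
    else:
        values = np.asarray(vector, dtype=float)
    out = model.forward(values)[0]
    if not np.all((out >= PLAUSIBLE_BP[0]) & (out <= PLAUSIBLE_BP[1])):
        warnings.warn(f"prediction {out} outside plausible BP range", stacklevel=2)
    return float(out[0]), float(out[1])


@dataclass
class EvaluationReport:
    """Signed-error summary of a model on a held-out test set."""

    errors: np.ndarray          # (n, 2) prediction - target, mmHg
    bin_edges: np.ndarray       # shared histogram edges, width 0.5 mmHg
    hist_sbp: np.ndarray
    hist_dbp: np.ndarray
    max_abs_error: float
    rmse: np.ndarray            # per output
    pearson_r: np.ndarray       # per output (nan when targets constant)
    p95_abs_error: float        # pooled over both outputs

    def to_dict(self) -> dict:
        return {
            "max_abs_error": self.max_abs_error,
            "rmse_sbp": float(self.rmse[0]),
            "rmse_dbp": float(self.rmse[1]),
            "pearson_sbp": float(self.pearson_r[0]),
            "pearson_dbp": float(self.pearson_r[1]),
            "p95_abs_error": self.p95_abs_error,
            "n_test": int(self.errors.shape[0]),
        }


def evaluate(model: BPModel, X_test: np.ndarray, y_test: np.ndarray) -> EvaluationReport:
    """Evaluate predictions on a test set disjoint from training."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if len(X_test) == 0:
        raise ParameterError("empty test set")
    pred = model.forward(X_test)
    errors = pred - y_test
    lim = max(np.abs(errors).max(), HIST_BIN_MMHG)
    edge = np.ceil(lim / HIST_BIN_MMHG) * HIST_BIN_MMHG
    bin_edges = np.arange(-edge, edge + HIST_BIN_MMHG / 2, HIST_BIN_MMHG)
    hist_sbp, _ = np.histogram(errors[:, 0], bins=bin_edges)
    hist_dbp, _ = np.histogram(errors[:, 1], bins=bin_edges)
    pearson = np.empty(2)
    for k in range(2):
        if np.std(y_test[:, k]) == 0 or np.std(pred[:, k]) == 0:
            pearson[k] = np.nan
        else:
            pearson[k] = np.corrcoef(pred[:, k], y_test[:, k])[0, 1]
    return EvaluationReport(
        errors=errors,
        bin_edges=bin_edges,
        hist_sbp=hist_sbp,
        hist_dbp=hist_dbp,
        max_abs_error=float(np.abs(errors).max()),
        rmse=np.sqrt(np.mean(errors**2, axis=0)),
        pearson_r=pearson,
        p95_abs_error=float(np.percentile(np.abs(errors).ravel(), 95)),
    )
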