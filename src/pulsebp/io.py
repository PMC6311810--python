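"""Readers and writers for the CSV/JSON artifacts exchanged between stages.

Record CSV dialect: comment header lines ``# fs=<Hz>`` (required) and
``# seed=<int>`` (optional), a column header ``amplitude``, then one sample
per line.  Ground truth travels in a JSON sidecar.  Sweep tables, feature
matrices and labels are plain CSV; models and reports are JSON with floats
at full double precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError, ParseError
from .features import FEATURE_NAMES
from .fusion_model import (
    BPModel,
    FeatureVector,
    NormStats,
    TrainConfig,
    TrainLog,
)
from .synthgen import PulseRecord, RecordTruth

__all__ = [
    "read_record",
    "write_record",
    "read_sweep",
    "write_sweep",
    "read_features",
    "write_features",
    "read_labels",
    "write_labels",
    "read_model",
    "write_model",
    "PipelineConfig",
]


def write_record(path, record: PulseRecord, seed: Optional[int] = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={float(record.fs)!r}\n")
        if seed is not None:
            fh.write(f"# seed={int(seed)}\n")
        fh.write("amplitude\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")
    if record.truth is not None:
        truth = {
            "sbp": record.truth.sbp,
            "dbp": record.truth.dbp,
            "onsets": [int(i) for i in record.truth.onsets],
        }
        path.with_suffix(path.suffix + ".truth.json").write_text(json.dumps(truth))


def read_record(path) -> PulseRecord:
    path = Path(path)
    fs = None
    samples = []
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        line = line.strip()
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            if key.strip() == "fs":
                try:
                    fs = float(value)
                except ValueError:
                    raise ParseError(f"{path}:{i + 1}: invalid fs value {value!r}")
            body_start = i + 1
        else:
            break
    if fs is None:
        raise ParseError(f"{path}:1: missing required '# fs=' header")
    for i, line in enumerate(lines[body_start:], start=body_start + 1):
        line = line.strip()
        if not line or line == "amplitude":
            continue
        fields = line.split(",")
        try:
            samples.append(float(fields[-1]))  # accepts time,amplitude too
        except ValueError:
            raise ParseError(f"{path}:{i}: cannot parse sample {line!r}")
    truth = None
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        truth = RecordTruth(
            sbp=d["sbp"], dbp=d["dbp"],
            onsets=np.asarray(d["onsets"], dtype=int), beat_params=[],
        )
    return PulseRecord(samples=np.asarray(samples), fs=fs, truth=truth)


def write_sweep(path, sweep: pd.DataFrame, bmi: Optional[float] = None) -> None:
    with Path(path).open("w") as fh:
        if bmi is not None:
            fh.write(f"# bmi={float(bmi)!r}\n")
        sweep.to_csv(fh, index=False)


def read_sweep(path) -> tuple[pd.DataFrame, Optional[float]]:
    path = Path(path)
    bmi = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            key, _, value = first.lstrip("# ").partition("=")
            if key.strip() == "bmi":
                bmi = float(value)
            sweep = pd.read_csv(fh)
        else:
            fh.seek(0)
            sweep = pd.read_csv(fh)
    if "level_N" not in sweep.columns:
        raise ParseError(f"{path}: sweep table lacks a level_N column")
    return sweep, bmi


def write_features(path, vectors: list[FeatureVector]) -> None:
    rows = [v.values for v in vectors]
    pd.DataFrame(rows, columns=list(FEATURE_NAMES)).to_csv(path, index=False)


def read_features(path) -> np.ndarray:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing feature columns {missing}")
    return df[list(FEATURE_NAMES)].to_numpy(dtype=float)


def write_labels(path, labels: np.ndarray) -> None:
    pd.DataFrame(np.asarray(labels), columns=["sbp", "dbp"]).to_csv(path, index=False)


def read_labels(path) -> np.ndarray:
    """Read (SBP, DBP) pairs; accepts a header line or bare ``120,80`` rows."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse labels: {exc}")
    first_col = str(df.columns[0])
    try:
        float(first_col)
    except ValueError:
        pass  # real header
    else:  # headerless file: first row was data
        df = pd.read_csv(path, header=None)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: labels must have exactly 2 columns")
    return df.to_numpy(dtype=float)


def write_model(path, model: BPModel) -> None:
    payload = {
        "architecture": list(model.architecture),
        "weights": {
            "w1": model.w1.tolist(), "b1": model.b1.tolist(),
            "w2": model.w2.tolist(), "b2": model.b2.tolist(),
        },
        "norm_stats": {
            "x_mean": model.x_stats.mean.tolist(),
            "x_scale": model.x_stats.scale.tolist(),
            "y_mean": model.y_stats.mean.tolist(),
            "y_scale": model.y_stats.scale.tolist(),
        },
        "config": asdict(model.config),
        "log": asdict(model.log),
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path) -> BPModel:
    d = json.loads(Path(path).read_text())
    ns = d["norm_stats"]
    x_mean = np.asarray(ns["x_mean"]); x_scale = np.asarray(ns["x_scale"])
    y_mean = np.asarray(ns["y_mean"]); y_scale = np.asarray(ns["y_scale"])
    return BPModel(
        w1=np.asarray(d["weights"]["w1"]),
        b1=np.asarray(d["weights"]["b1"]),
        w2=np.asarray(d["weights"]["w2"]),
        b2=np.asarray(d["weights"]["b2"]),
        x_stats=NormStats(x_mean, x_scale, x_scale == 0),
        y_stats=NormStats(y_mean, y_scale, y_scale == 0),
        architecture=tuple(d["architecture"]),
        config=TrainConfig(**d["config"]),
        log=TrainLog(**d["log"]),
    )


_CONFIG_RANGES = {
    "fs": (100.0, 10000.0),
    "band_low": (0.01, 5.0),
    "band_high": (5.0, 100.0),
    "fft_window_beats": (2, 20),
    "hidden": (1, 500),
    "max_iter": (1, 100000),
    "patience": (1, 1000),
    "seed": (0, 2**31 - 1),
}


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline."""

    fs: float = 500.0
    band_low: float = 0.15
    band_high: float = 25.0
    fft_window_beats: int = 5
    split_fractions: tuple = (0.7, 0.15, 0.15)
    seed: int = 0
    hidden: int = 30
    max_iter: int = 1000
    patience: int = 6
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in _CONFIG_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ParameterError(f"config {name}={v} outside [{lo}, {hi}]")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ParameterError("split_fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ParameterError("config file must be a key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)
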