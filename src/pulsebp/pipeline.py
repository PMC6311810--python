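"""End-to-end orchestration: records in, evaluation report out.

Executes condition -> segment -> fiducials -> features -> QC -> normalize ->
train -> evaluate in order, writing every intermediate artifact, and logs
per-stage counts.  Each labels row pairs with one record; all feature
windows of a record inherit that record's (SBP, DBP) label.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io
from .errors import DataError, ParameterError, PulseBPError
from .features import build_windows
from .fusion_model import (
    FeatureVector,
    ThresholdMatrix,
    TrainConfig,
    evaluate,
    qc_filter,
    split_data,
    train_ann,
)
from .preprocess import condition_signal, segment_beats

logger = logging.getLogger("pulsebp")

__all__ = ["run_pipeline"]


class StageError(PulseBPError):
    """Wraps a stage failure with the stage name and record id."""

    def __init__(self, stage: str, record_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on record {record_id!r}: {cause}")
        self.stage = stage
        self.record_id = record_id
        self.cause = cause


def run_pipeline(config: io.PipelineConfig, record_paths, label_path, out_dir) -> dict:
    """Run the full training pipeline over a set of record files.

    Returns the evaluation report as a dict; writes ``features.csv``,
    ``labels_used.csv``, ``model.json`` and ``report.json`` under
    ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = io.read_labels(label_path)
    record_paths = list(record_paths)
    if len(labels) != len(record_paths):
        raise ParameterError(
            f"{len(record_paths)} records but {len(labels)} label rows"
        )

    vectors: list[FeatureVector] = []
    y_rows = []
    counts = {"records": len(record_paths), "beats": 0, "windows": 0}
    for rec_path, label in zip(record_paths, labels):
        rec_id = str(rec_path)
        record = io.read_record(rec_path)
        stage = "condition"
        try:
            conditioned = condition_signal(record.samples, record.fs)
            stage = "segment"
            beats = segment_beats(conditioned, record.fs)
            counts["beats"] += len(beats)
            stage = "features"
            windows = build_windows(
                beats, record.fs,
                beats_per_window=config.fft_window_beats, skip_first=1,
            )
        except (DataError, ParameterError) as exc:
            raise StageError(stage, rec_id, exc) from exc
        for wf in windows:
            vectors.append(FeatureVector.from_window(wf, window_id=len(vectors)))
            y_rows.append(label)
        counts["windows"] += len(windows)

    tm = ThresholdMatrix.default()
    if config.thresholds:
        tm.bounds.update({k: tuple(v) for k, v in config.thresholds.items()})
    accepted, rejections = qc_filter(vectors, tm)
    mask = [v.qc_pass for v in vectors]
    y = np.asarray(y_rows, dtype=float)[mask]
    counts["accepted"] = len(accepted)
    counts["rejected"] = dict(rejections)
    logger.info("pipeline counts: %s", counts)

    io.write_features(out_dir / "features.csv", accepted)
    io.write_labels(out_dir / "labels_used.csv", y)

    X = np.vstack([v.values for v in accepted])
    split = split_data(len(X), fractions=config.split_fractions, seed=config.seed)
    model = train_ann(
        (X[split.train], y[split.train]),
        (X[split.validation], y[split.validation]),
        TrainConfig(
            hidden=config.hidden, seed=config.seed,
            max_iter=config.max_iter, patience=config.patience,
        ),
    )
    io.write_model(out_dir / "model.json", model)
    report = evaluate(model, X[split.test], y[split.test]).to_dict()
    report["counts"] = counts
    import json

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
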