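"""Two-stage prediction: a binary resistance gate, then 7-class assignment.

Stage 1 is a binary SVM separating herbicide-resistant from non-resistant
sequences; stage 2 is a one-vs-one multi-class SVM over the seven
herbicide-target enzyme classes (ACCase, ALS, EPSPS, GS, HPPD, PDS, PPO).
The gate is strict: a query predicted non-resistant in stage 1 is final and
never reaches stage 2; queries predicted resistant receive the argmax
stage-2 class.  The reported probability is the probability of the assigned
class at the stage that assigned it.

A single-stage 8-class alternative (seven resistant classes plus
non-resistant in one one-vs-one model) is provided for comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import KmerEncodingSpec, _encode_one
from .seqio import LabeledDataset, SequenceRecord
from .svm_core import (
    KernelConfig,
    MODEL_FORMAT_VERSION,
    MulticlassModel,
    SvmModel,
    _model_from_dict,
    _model_to_dict,
    _multiclass_from_dict,
    _multiclass_to_dict,
    decision_values,
    predict_proba_binary,
    predict_proba_multiclass,
    train_binary_svm,
    train_multiclass,
)

__all__ = [
    "RESISTANT_CLASSES",
    "RESISTANT",
    "NON_RESISTANT",
    "TwoStageModel",
    "PredictionRow",
    "train_two_stage",
    "predict_two_stage",
    "train_single_stage",
    "save_two_stage",
    "load_two_stage",
    "rows_to_tsv",
]

RESISTANT_CLASSES: tuple[str, ...] = (
    "ACCase", "ALS", "EPSPS", "GS", "HPPD", "PDS", "PPO",
)
RESISTANT = "resistant"
NON_RESISTANT = "non-resistant"


@dataclass
class TwoStageModel:
    """Fitted binary gate + 7-class assigner, each with its encoding spec."""

    stage1: SvmModel
    stage1_spec: KmerEncodingSpec
    stage2: MulticlassModel
    stage2_spec: KmerEncodingSpec
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PredictionRow:
    """One row of the tabular prediction report."""

    seq_number: int              # 1-based position in the query batch
    id: str
    predicted_class: str | None  # one of the 8 labels, or None when failed
    probability: float | None    # probability of the assigned class
    stage: int | None            # stage (1 or 2) that assigned the class
    failed: bool = False


def train_two_stage(
    binary_data: LabeledDataset,
    multi_data: LabeledDataset,
    spec: KmerEncodingSpec = KmerEncodingSpec(),
    config: KernelConfig = KernelConfig(),
    seed: int = 0,
    *,
    stage2_spec: KmerEncodingSpec | None = None,
) -> TwoStageModel:
    """Fit both stages with probability calibration.

    ``binary_data`` must carry the labels {resistant, non-resistant};
    ``multi_data`` must contain all seven target-enzyme classes with at
    least two members each.
    """
    from .features import encode_dataset

    binary_labels = set(binary_data.labels)
    if binary_labels != {RESISTANT, NON_RESISTANT}:
        raise ValueError(
            f"stage-1 data must have labels {{{RESISTANT}, {NON_RESISTANT}}}, "
            f"got {sorted(binary_labels)}"
        )
    missing = sorted(set(RESISTANT_CLASSES) - set(multi_data.labels))
    if missing:
        raise ValueError(f"stage-2 data is missing class(es): {missing}")
    extra = sorted(set(multi_data.labels) - set(RESISTANT_CLASSES))
    if extra:
        raise ValueError(f"stage-2 data has labels outside the 7 classes: {extra}")
    stage2_spec = stage2_spec or spec

    fm1, _ = encode_dataset(binary_data, spec)
    stage1 = train_binary_svm(
        fm1.values, binary_data.labels, config, pos_label=RESISTANT, calibrate=True
    )
    fm2, _ = encode_dataset(multi_data, stage2_spec)
    stage2 = train_multiclass(fm2.values, multi_data.labels, config, calibrate=True)
    metadata = {
        "seed": seed,
        "n_binary": len(binary_data),
        "n_multi": len(multi_data),
        "multi_class_sizes": {
            c: multi_data.labels.count(c) for c in RESISTANT_CLASSES
        },
    }
    return TwoStageModel(stage1, spec, stage2, stage2_spec, metadata)


def predict_two_stage(
    model: TwoStageModel, records: Sequence[SequenceRecord]
) -> list[PredictionRow]:
    """Predict a batch of records through the strict two-stage gate.

    Row order follows the input; a record that cannot be encoded under
    either stage's spec yields a row flagged failed rather than aborting
    the batch.  Empty input is an error.
    """
    records = list(records)
    if not records:
        raise ValueError("predict_two_stage requires at least one record")
    rows: list[PredictionRow] = []
    for number, rec in enumerate(records, start=1):
        try:
            x1 = _encode_one(rec.residues, model.stage1_spec)
            x2 = _encode_one(rec.residues, model.stage2_spec)
        except ValueError:
            rows.append(PredictionRow(number, rec.id, None, None, None, failed=True))
            continue
        d = float(decision_values(model.stage1, x1[None, :])[0])
        p_resistant = float(predict_proba_binary(model.stage1, x1[None, :])[0])
        if d < 0:   # gate: non-resistant is final, stage 2 never invoked
            rows.append(
                PredictionRow(number, rec.id, NON_RESISTANT, 1.0 - p_resistant, 1)
            )
            continue
        proba = predict_proba_multiclass(model.stage2, x2[None, :])[0]
        best = int(np.argmax(proba))
        rows.append(
            PredictionRow(
                number, rec.id, model.stage2.classes[best], float(proba[best]), 2
            )
        )
    return rows


def train_single_stage(
    eight_class_data: LabeledDataset,
    spec: KmerEncodingSpec = KmerEncodingSpec(),
    config: KernelConfig = KernelConfig(),
    seed: int = 0,
) -> MulticlassModel:
    """Fit the single-stage 8-class one-vs-one model (28 pairwise SVMs)."""
    from .features import encode_dataset

    expected = set(RESISTANT_CLASSES) | {NON_RESISTANT}
    missing = sorted(expected - set(eight_class_data.labels))
    if missing:
        raise ValueError(f"8-class data is missing class(es): {missing}")
    fm, _ = encode_dataset(eight_class_data, spec)
    return train_multiclass(fm.values, eight_class_data.labels, config, calibrate=True)


def save_two_stage(model: TwoStageModel, path: str | Path) -> None:
    """Serialize a two-stage model to one versioned JSON file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "type": "two_stage",
        "stage1": _model_to_dict(model.stage1),
        "stage1_spec": model.stage1_spec.to_dict(),
        "stage2": _multiclass_to_dict(model.stage2),
        "stage2_spec": model.stage2_spec.to_dict(),
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_two_stage(path: str | Path) -> TwoStageModel:
    """Load a model saved by :func:`save_two_stage`; version-checked."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    if payload.get("type") != "two_stage":
        raise ValueError(f"not a two-stage model file: {payload.get('type')!r}")
    return TwoStageModel(
        stage1=_model_from_dict(payload["stage1"]),
        stage1_spec=KmerEncodingSpec.from_dict(payload["stage1_spec"]),
        stage2=_multiclass_from_dict(payload["stage2"]),
        stage2_spec=KmerEncodingSpec.from_dict(payload["stage2_spec"]),
        metadata=payload["metadata"],
    )


def rows_to_tsv(rows: Sequence[PredictionRow], path: str | Path) -> None:
    """Write the tabular report: seq_number, id, predicted_class, probability, stage."""
    with open(path, "w") as fh:
        fh.write("seq_number\tid\tpredicted_class\tprobability\tstage\n")
        for r in rows:
            cls = "failed" if r.failed else r.predicted_class
            prob = "" if r.probability is None else f"{r.probability:.6f}"
            stage = "" if r.stage is None else str(r.stage)
            fh.write(f"{r.seq_number}\t{r.id}\t{cls}\t{prob}\t{stage}\n")
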