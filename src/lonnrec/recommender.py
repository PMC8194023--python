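"""Dual-model therapy recommendation with binary confidence.

Two LONNs are trained on the same schema and normalization: ``model_full`` on
the whole cohort and ``model_positive`` on the positive-outcome subset
(survivors with long therapy times).  For a new patient both models predict a
treatment key; if their binarised keys agree the full-data model's prediction
is returned with confidence 1, otherwise the positive-outcome model's
prediction is returned with confidence 0 and the full model's prediction is
attached as the alternative.  Every recommendation can be appended to an
append-only CSV log, regardless of whether the physician accepts it.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    INPUT_VARS,
    BINARY_VARS,
    NormalizationSpec,
    encode_and_normalize,
    filter_positive,
)
from .exceptions import SchemaError
from .network import LonnModel, LonnSpec, TrainConfig, TrainingHistory, build_lonn, train

__all__ = [
    "Recommendation",
    "RecommenderPair",
    "log_recommendation",
    "recommend",
    "train_pair",
]

LOG_COLUMNS = [
    "timestamp",
    "patient_id",
    "tk",
    "time_days",
    "confidence",
    "alt_tk",
    "alt_time_days",
    "source_model",
    "accepted",
]


@dataclass
class RecommenderPair:
    """The two trained models plus the shared normalization."""

    model_full: LonnModel
    model_positive: LonnModel
    norm_spec: NormalizationSpec
    lonn_spec: Optional[LonnSpec] = None
    train_config: Optional[TrainConfig] = None
    history_full: Optional[TrainingHistory] = None
    history_positive: Optional[TrainingHistory] = None


@dataclass
class Recommendation:
    """One therapy recommendation for one patient.

    ``confidence`` is 1 exactly when both models agree on the binarised
    treatment key; ``alternative`` carries the other model's (key, time) only
    in the low-confidence case.
    """

    patient_id: str
    treatment_key: int
    therapy_time_days: float
    confidence: int
    source_model: str
    alternative: Optional[Tuple[int, float]] = None

    def __post_init__(self):
        if self.confidence not in (0, 1):
            raise ValueError("confidence must be binary")
        if self.confidence == 1 and self.alternative is not None:
            raise ValueError("alternative must be absent when confidence = 1")


def train_pair(
    cohort: Cohort,
    lonn_spec: Optional[LonnSpec] = None,
    train_config: Optional[TrainConfig] = None,
    min_time_days: float = 60.0,
) -> RecommenderPair:
    """Train the full-cohort and positive-outcome models with one shared
    normalization (fitted on the full training cohort)."""
    lonn_spec = lonn_spec or LonnSpec()
    train_config = train_config or TrainConfig()
    positive = filter_positive(cohort, min_time_days=min_time_days)
    if len(positive) == 0:
        raise SchemaError(
            "positive-outcome subset is empty; lower min_time_days or check the "
            "death flags"
        )
    X_full, Y_full, norm_spec = encode_and_normalize(cohort)
    X_pos, Y_pos, _ = encode_and_normalize(positive, spec=norm_spec)

    model_full = build_lonn(lonn_spec)
    model_positive = build_lonn(lonn_spec)
    model_full.input_names = list(INPUT_VARS)
    model_positive.input_names = list(INPUT_VARS)
    hist_full = train(model_full, X_full, Y_full, train_config)
    hist_pos = train(model_positive, X_pos, Y_pos, train_config)
    return RecommenderPair(
        model_full=model_full,
        model_positive=model_positive,
        norm_spec=norm_spec,
        lonn_spec=lonn_spec,
        train_config=train_config,
        history_full=hist_full,
        history_positive=hist_pos,
    )


def _encode_patient(patient, norm_spec: NormalizationSpec) -> np.ndarray:
    if isinstance(patient, pd.Series):
        patient = patient.to_dict()
    missing = [v for v in INPUT_VARS if v not in patient or pd.isna(patient[v])]
    if missing:
        raise SchemaError(f"patient is missing covariate(s): {missing}")
    feats = []
    for var in INPUT_VARS:
        val = float(patient[var])
        if var in BINARY_VARS:
            feats.append(val)
        else:
            feats.append(float(norm_spec.transform_column(var, np.array([val]))[0]))
    return np.array(feats).reshape(1, -1)


def recommend(pair: RecommenderPair, patient, threshold: float = 0.5) -> Recommendation:
    """Apply the dual-model rule to one patient (mapping or Series with V1-V10)."""
    x = _encode_patient(patient, pair.norm_spec)
    pred_full = pair.model_full.predict(x)[0]
    pred_pos = pair.model_positive.predict(x)[0]
    tk_full = int(pred_full[1] >= threshold)
    tk_pos = int(pred_pos[1] >= threshold)
    pid = str(patient.get("ID", "") if hasattr(patient, "get") else patient["ID"])
    if tk_full == tk_pos:
        return Recommendation(
            patient_id=pid,
            treatment_key=tk_full,
            therapy_time_days=pair.norm_spec.inverse_transform("time", pred_full[0]),
            confidence=1,
            source_model="model_full",
        )
    return Recommendation(
        patient_id=pid,
        treatment_key=tk_pos,
        therapy_time_days=pair.norm_spec.inverse_transform("time", pred_pos[0]),
        confidence=0,
        source_model="model_positive",
        alternative=(
            tk_full,
            pair.norm_spec.inverse_transform("time", pred_full[0]),
        ),
    )


def log_recommendation(
    recommendation: Recommendation,
    store_path,
    accepted: Optional[bool] = None,
) -> dict:
    """Append the recommendation to an append-only CSV log; returns the row."""
    row = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "patient_id": recommendation.patient_id,
        "tk": recommendation.treatment_key,
        "time_days": f"{recommendation.therapy_time_days:.4f}",
        "confidence": recommendation.confidence,
        "alt_tk": "" if recommendation.alternative is None else recommendation.alternative[0],
        "alt_time_days": (
            "" if recommendation.alternative is None
            else f"{recommendation.alternative[1]:.4f}"
        ),
        "source_model": recommendation.source_model,
        "accepted": "" if accepted is None else int(accepted),
    }
    new_file = not os.path.exists(store_path) or os.path.getsize(store_path) == 0
    with open(store_path, "a", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=LOG_COLUMNS)
        if new_file:
            writer.writeheader()
        writer.writerow(row)
    return row
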