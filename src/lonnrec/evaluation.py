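"""Evaluation metrics and the model-validation experiments.

Metrics follow the study's reporting conventions: the *training error* is the
mean absolute error on the normalised outputs, expressed in percent; therapy
prediction is scored with accuracy/precision/recall at threshold 0.5 on the
binary treatment key; the therapy-time error is the root-mean-square error on
the normalised time, again in percent.

The experiments are (a) a beta sweep: train a fresh LONN per (beta_int, seed)
for 50 epochs and tabulate the mean training error per beta; (b) a topology
comparison of the dense ReLU baseline against LONN variants on a shared split;
and (c) the parameter-hierarchy ranking: input importance read off the first
trainable layer as the normalised column sums of absolute weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import Cohort, INPUT_VARS, encode_and_normalize, split_train_test
from .exceptions import InvalidInputError, InvalidParameterError, ShapeError
from .network import (
    LonnModel,
    LonnSpec,
    TrainConfig,
    build_dense_baseline,
    build_lonn,
    train,
)

__all__ = [
    "MetricsReport",
    "beta_sweep",
    "classification_metrics",
    "compare_models",
    "evaluate_model",
    "input_importance",
    "time_rms",
    "training_error",
]


@dataclass
class MetricsReport:
    """Percent-scale metrics in the study's reporting shape."""

    training_error: float
    therapy_accuracy: float
    precision: Optional[float]
    recall: float
    time_rms: float
    n_samples: int


def training_error(model: LonnModel, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean absolute error over samples and outputs, x100 (normalised scale)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.size == 0:
        raise InvalidInputError("empty data")
    pred = model.predict(X)
    return float(np.mean(np.abs(Y - pred))) * 100.0


def classification_metrics(
    tk_probs: Sequence[float], tk_labels: Sequence[float], threshold: float = 0.5
) -> Tuple[float, Optional[float], float]:
    """(accuracy, precision, recall) in percent on the positive treatment-key class.

    Precision is ``None`` (absent) when the model makes no positive
    predictions, rather than a misleading 0.
    """
    probs = np.asarray(tk_probs, dtype=float)
    labels = np.asarray(tk_labels, dtype=float)
    if probs.shape != labels.shape:
        raise ShapeError("tk_probs and tk_labels must have the same length")
    if probs.size == 0:
        raise InvalidInputError("empty data")
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise InvalidInputError("labels must be binary")
    pred = (probs >= threshold).astype(int)
    lab = labels.astype(int)
    tp = int(np.sum((pred == 1) & (lab == 1)))
    fp = int(np.sum((pred == 1) & (lab == 0)))
    fn = int(np.sum((pred == 0) & (lab == 1)))
    accuracy = float(np.mean(pred == lab)) * 100.0
    precision = None if tp + fp == 0 else 100.0 * tp / (tp + fp)
    recall = 100.0 if tp + fn == 0 else 100.0 * tp / (tp + fn)
    return accuracy, precision, recall


def time_rms(time_pred_norm: Sequence[float], time_label_norm: Sequence[float]) -> float:
    """Root-mean-square error on the normalised time, x100."""
    pred = np.asarray(time_pred_norm, dtype=float)
    lab = np.asarray(time_label_norm, dtype=float)
    if pred.shape != lab.shape:
        raise ShapeError("prediction and label vectors must have the same length")
    if pred.size == 0:
        raise InvalidInputError("empty data")
    return float(np.sqrt(np.mean((pred - lab) ** 2))) * 100.0


def evaluate_model(
    model: LonnModel,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    threshold: float = 0.5,
) -> MetricsReport:
    """Training error on the training split; therapy and time metrics on test."""
    pred_test = model.predict(X_test)
    acc, prec, rec = classification_metrics(pred_test[:, 1], Y_test[:, 1], threshold)
    return MetricsReport(
        training_error=training_error(model, X_train, Y_train),
        therapy_accuracy=acc,
        precision=prec,
        recall=rec,
        time_rms=time_rms(pred_test[:, 0], Y_test[:, 0]),
        n_samples=int(Y_test.shape[0]),
    )


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def beta_sweep(
    cohort: Cohort,
    beta_values: Sequence[float],
    epochs: int = 50,
    seeds: Sequence[int] = (0, 1, 2),
    base_spec: Optional[LonnSpec] = None,
    base_config: Optional[TrainConfig] = None,
    plot_path=None,
) -> pd.DataFrame:
    """Mean training error per ``beta_int`` after ``epochs`` epochs.

    A fresh default LONN is built and trained per (beta, seed); rows hold the
    per-beta mean and standard deviation over seeds.
    """
    beta_values = [float(b) for b in beta_values]
    if any(b == 0.0 for b in beta_values):
        raise InvalidParameterError("beta values must be nonzero")
    base_spec = base_spec or LonnSpec()
    base_config = base_config or TrainConfig()
    X, Y, _ = encode_and_normalize(cohort)
    rows = []
    for beta in beta_values:
        errs = []
        for seed in seeds:
            spec = replace(base_spec, beta_int=beta, seed=int(seed))
            config = replace(base_config, epochs=epochs, shuffle_seed=int(seed))
            model = build_lonn(spec)
            history = train(model, X, Y, config)
            errs.append(history.training_errors[-1])
        rows.append(
            {
                "beta_int": beta,
                "training_error_mean": float(np.mean(errs)),
                "training_error_sd": float(np.std(errs)),
                "n_seeds": len(list(seeds)),
            }
        )
    table = pd.DataFrame(rows)
    if plot_path is not None:
        _plot_beta_sweep(table, plot_path)
    return table


def _plot_beta_sweep(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        table["beta_int"],
        table["training_error_mean"],
        yerr=table["training_error_sd"],
        fmt="o-",
    )
    ax.set_xlabel(r"$\beta_{int}$")
    ax.set_ylabel("training error (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_models(
    cohort: Cohort,
    specs: Optional[Dict[str, Optional[LonnSpec]]] = None,
    config: Optional[TrainConfig] = None,
    split_seed: int = 0,
    train_fraction: float = 0.8,
) -> pd.DataFrame:
    """Train each named architecture on the same shuffled split; tabulate metrics.

    ``specs`` maps a row name to a ``LonnSpec`` (or ``None`` for the dense
    ReLU baseline).  Defaults to the baseline, the 4-M-node reference LONN and
    a 10-M-node widened LONN.
    """
    if specs is None:
        specs = {
            "dense_baseline": None,
            "lonn_4m": LonnSpec(),
            "lonn_10m": LonnSpec(m_layer_width=10, and_layer_width=9),
        }
    config = config or TrainConfig()
    train_c, test_c = split_train_test(cohort, train_fraction, seed=split_seed)
    X_tr, Y_tr, norm = encode_and_normalize(train_c)
    X_te, Y_te, _ = encode_and_normalize(test_c, spec=norm)
    rows = []
    for name, spec in specs.items():
        if spec is None:
            model = build_dense_baseline(seed=split_seed)
        else:
            model = build_lonn(spec)
        train(model, X_tr, Y_tr, config)
        report = evaluate_model(model, X_tr, Y_tr, X_te, Y_te)
        rows.append(
            {
                "model": name,
                "training_error": report.training_error,
                "therapy_accuracy": report.therapy_accuracy,
                "precision": report.precision,
                "recall": report.recall,
                "time_rms": report.time_rms,
                "n_test": report.n_samples,
            }
        )
    return pd.DataFrame(rows)


def input_importance(
    model: LonnModel, input_names: Optional[List[str]] = None
) -> List[Tuple[str, float]]:
    """Parameter hierarchy: normalised absolute-weight column sums of the
    first trainable layer, ranked descending (stable tie-break by column)."""
    first = next((ly for ly in model.layers if ly.trainable), None)
    if first is None:
        raise InvalidParameterError("model has no trainable first layer")
    scores = np.abs(first.weights).sum(axis=0)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    names = input_names or model.input_names or [
        INPUT_VARS[j] if j < len(INPUT_VARS) else f"x{j}" for j in range(first.fan_in)
    ]
    if len(names) != first.fan_in:
        raise ShapeError("input_names length must match the first layer fan-in")
    order = sorted(range(len(names)), key=lambda j: (-scores[j], j))
    return [(names[j], float(scores[j])) for j in order]
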