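"""Performance metrics and the SNR-robustness sweep.

Accuracy = trace / total; Cohen's kappa = (p_o - p_e) / (1 - p_e) with
p_e from the marginals; per-class TPR/TNR from the one-vs-rest collapse.
Undefined rates raise ``UndefinedMetricError`` (reported as null in the
JSON report, never silently 0).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

N_CLASSES = 8


class UndefinedMetricError(ValueError):
    """Raised when a requested rate has an empty denominator."""


def confusion_matrix(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Counts with rows = true class, cols = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def cohens_kappa(cm: np.ndarray) -> float:
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float(np.sum(cm.sum(axis=1) * cm.sum(axis=0)) / total**2)
    if p_e >= 1.0:
        raise UndefinedMetricError("kappa undefined: both raters constant (p_e = 1)")
    return float((p_o - p_e) / (1.0 - p_e))


def _ovr(cm: np.ndarray, class_c: int):
    cm = np.asarray(cm)
    tp = cm[class_c, class_c]
    fn = cm[class_c].sum() - tp
    fp = cm[:, class_c].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return tp, fn, fp, tn


def sensitivity(cm: np.ndarray, class_c: int) -> float:
    """TPR = TP / (TP + FN)."""
    tp, fn, _, _ = _ovr(cm, class_c)
    if tp + fn == 0:
        raise UndefinedMetricError(f"class {class_c} has no positive samples")
    return float(tp / (tp + fn))


def specificity(cm: np.ndarray, class_c: int) -> float:
    """TNR = TN / (TN + FP)."""
    _, _, fp, tn = _ovr(cm, class_c)
    if tn + fp == 0:
        raise UndefinedMetricError(f"class {class_c} has no negative samples")
    return float(tn / (tn + fp))


@dataclasses.dataclass
class MetricsReport:
    accuracy: float
    kappa: float
    per_class_tpr: List[Optional[float]]
    per_class_tnr: List[Optional[float]]
    confusion: np.ndarray
    n: int
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def per_class_accuracy(self) -> List[Optional[float]]:
        # per-class accuracy is reported as recall (one-vs-rest collapse)
        return self.per_class_tpr

    def to_json(self) -> str:
        return json.dumps(
            {
                "accuracy": self.accuracy,
                "kappa": self.kappa,
                "per_class_tpr": self.per_class_tpr,
                "per_class_tnr": self.per_class_tnr,
                "per_class_accuracy": self.per_class_accuracy,
                "confusion": self.confusion.tolist(),
                "n": self.n,
                "provenance": self.provenance,
            },
            indent=2,
        )


def metrics_report(y_true, y_pred, provenance: Optional[dict] = None) -> MetricsReport:
    cm = confusion_matrix(y_true, y_pred)

    def safe(fn, c):
        try:
            return fn(cm, c)
        except UndefinedMetricError:
            return None

    return MetricsReport(
        accuracy=accuracy(cm),
        kappa=cohens_kappa(cm),
        per_class_tpr=[safe(sensitivity, c) for c in range(N_CLASSES)],
        per_class_tnr=[safe(specificity, c) for c in range(N_CLASSES)],
        confusion=cm,
        n=int(cm.sum()),
        provenance=provenance or {},
    )


DEFAULT_SNRS = tuple(range(5, 55, 5))


def noise_robustness_sweep(
    predict_fn: Callable[[Optional[float], int], tuple],
    snrs: Sequence[Optional[float]] = DEFAULT_SNRS,
    n_reps: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean +- SD of accuracy/kappa per SNR over independent noise draws.

    ``predict_fn(snr_db, rng_seed)`` must run the full corrupt -> filter ->
    tensorize -> predict chain and return (y_true, y_pred).  ``snr_db=None``
    (or inf) means the clean signal; those reps are deterministic.
    Returns (summary per SNR, per-repetition records).
    """
    if len(snrs) == 0:
        raise ValueError("snrs must be non-empty")
    root = np.random.SeedSequence(seed)
    records = []
    for snr in snrs:
        sub = root.spawn(1)[0]
        rep_seeds = sub.generate_state(n_reps)
        for rep in range(n_reps):
            y_true, y_pred = predict_fn(snr, int(rep_seeds[rep]))
            cm = confusion_matrix(y_true, y_pred)
            records.append(
                {
                    "snr_db": np.inf if snr is None else snr,
                    "rep": rep,
                    "accuracy": accuracy(cm),
                    "kappa": cohens_kappa(cm),
                    "n": int(cm.sum()),
                }
            )
    rec = pd.DataFrame.from_records(records)
    summary = (
        rec.groupby("snr_db")
        .agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", "std"),
            kappa_mean=("kappa", "mean"),
            kappa_sd=("kappa", "std"),
            n_reps=("rep", "count"),
        )
        .reset_index()
    )
    summary[["accuracy_sd", "kappa_sd"]] = summary[["accuracy_sd", "kappa_sd"]].fillna(0.0)
    return summary, rec


def plot_confusion(cm: np.ndarray, path, class_names: Optional[List[str]] = None) -> None:
    """Optional heat-map rendering (matplotlib imported lazily)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = class_names or [str(i) for i in range(cm.shape[0])]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm, cmap="Blues")
    ax.set_xticks(range(len(names)), names)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center", fontsize=8)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
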