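"""Model scoring: accuracy, confusion matrix, and per-class ROC/AUC.

The ROC curve per class is one-vs-rest over that class's score column,
swept across all score thresholds and integrated with the trapezoidal
rule. Accuracy comes from argmax predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix, roc_curve

from .dataset_builder import FeatureDataset
from .models import TrainedModel, predict_proba


@dataclass
class EvaluationReport:
    accuracy: float
    confusion: np.ndarray  # rows = true class, columns = predicted class
    auc_per_class: dict[int, float]
    n_test: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "auc_per_class": {str(k): v for k, v in self.auc_per_class.items()},
            "n_test": self.n_test,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def _auc_one_vs_rest(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal AUC over the threshold-swept ROC for one class."""
    if y_true.all() or not y_true.any():
        return float("nan")  # degenerate: only one class present
    fpr, tpr, _ = roc_curve(y_true.astype(int), scores)
    return float(np.trapezoid(tpr, fpr))


def evaluate_model(model: TrainedModel, test: FeatureDataset) -> EvaluationReport:
    """Score a trained model on a held-out feature dataset."""
    if test.n_samples == 0:
        raise ValueError("test set is empty")
    proba = predict_proba(model, test.features)
    preds = proba.argmax(axis=1)
    y = np.asarray(test.labels, dtype=int)
    confusion = confusion_matrix(y, preds, labels=[0, 1])
    accuracy = float(np.trace(confusion)) / test.n_samples
    auc = {
        c: _auc_one_vs_rest(y == c, proba[:, c]) for c in (0, 1)
    }
    return EvaluationReport(accuracy, confusion, auc, test.n_samples)


def plot_report(report: EvaluationReport, out_dir: str | Path) -> list[Path]:
    """Render the confusion matrix as a heatmap; returns written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(report.confusion, cmap="Blues")
    for (i, j), v in np.ndenumerate(report.confusion):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"accuracy = {report.accuracy:.3f}")
    path = out_dir / "confusion_matrix.png"
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return [path]
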