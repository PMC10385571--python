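"""Forecast-quality and classification metrics.

Forecast quality is measured by the root-mean-square error and the Pearson
correlation coefficient between forecast and ground truth.  Classification
quality uses per-class one-vs-rest counts: accuracy (Tp+Tn)/(Tp+Tn+Fp+Fn),
precision Tp/(Tp+Fp) and F1 = Tp/(Tp + (Fp+Fn)/2), plus macro averages and
the full confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


def rmse(y: np.ndarray, yhat: np.ndarray, per_channel: bool = False):
    """Root-mean-square error; symmetric in its arguments.

    With ``per_channel=True`` (inputs of shape (n, channels)) returns
    (per-channel vector, their mean) instead of the pooled scalar.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    if per_channel:
        if y.ndim != 2:
            raise ValueError("per_channel requires (samples, channels) input")
        vals = np.sqrt(np.mean((y - yhat) ** 2, axis=0))
        return vals, float(vals.mean())
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def corr(y: np.ndarray, yhat: np.ndarray, per_channel: bool = False):
    """Pearson correlation coefficient in [-1, 1].

    Raises on zero-variance input (the coefficient is undefined there) rather
    than silently returning 0.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    if per_channel:
        if y.ndim != 2:
            raise ValueError("per_channel requires (samples, channels) input")
        vals = np.array([corr(y[:, c], yhat[:, c]) for c in range(y.shape[1])])
        return vals, float(vals.mean())
    a = y.ravel() - y.mean()
    b = yhat.ravel() - yhat.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.clip(np.sum(a * b) / denom, -1.0, 1.0))


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = true class, columns = predicted) and derived
    per-class / macro metrics."""

    confusion: np.ndarray
    label_names: list[str]
    accuracy: float
    per_class_accuracy: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_f1: float

    def to_dict(self) -> dict:
        return {
            "label_names": list(self.label_names),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "precision": self.precision.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"overall accuracy: {self.accuracy:.4f}",
                 f"macro precision:  {self.macro_precision:.4f}",
                 f"macro F1:         {self.macro_f1:.4f}", "",
                 "class\tprecision\tF1\taccuracy"]
        for i, name in enumerate(self.label_names):
            lines.append(
                f"{name}\t{self.precision[i]:.4f}\t{self.f1[i]:.4f}"
                f"\t{self.per_class_accuracy[i]:.4f}"
            )
        return "\n".join(lines)


def classification_report(true_labels, pred_labels, n_classes: int,
                          label_names: list[str] | None = None
                          ) -> ClassificationReport:
    """Confusion matrix plus one-vs-rest accuracy, precision and F1.

    Per-class precision/F1 for a class with no predicted (or no true)
    positives is taken as 0.  Macro averages are unweighted means over
    classes.
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.shape} vs {p.shape}")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    with np.errstate(divide="ignore", invalid="ignore"):
        per_class_acc = np.where(total > 0, (tp + tn) / total, 0.0)
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        f1 = np.where(tp + 0.5 * (fp + fn) > 0,
                      tp / (tp + 0.5 * (fp + fn)), 0.0)
    names = label_names if label_names is not None else [
        str(i) for i in range(n_classes)
    ]
    return ClassificationReport(
        confusion=cm,
        label_names=list(names),
        accuracy=float(tp.sum() / total) if total else 0.0,
        per_class_accuracy=per_class_acc,
        precision=precision,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_f1=float(f1.mean()),
    )


def forecast_report(pairs, forecasts) -> dict:
    """Per-activity and overall RMSE/CORR for a list of epoch pairs.

    For each epoch, RMSE and CORR are computed per channel and averaged;
    per-activity values average over that activity's epochs, and the grand
    mean averages over activities.
    """
    by_activity: dict[str, list[tuple[float, float]]] = {}
    for pair, fc in zip(pairs, forecasts):
        _, r = rmse(pair.future, fc, per_channel=True)
        _, c = corr(pair.future, fc, per_channel=True)
        by_activity.setdefault(pair.label, []).append((r, c))
    out: dict = {"per_activity": {}}
    for label in sorted(by_activity):
        vals = np.array(by_activity[label])
        out["per_activity"][label] = {
            "rmse": float(vals[:, 0].mean()),
            "corr": float(vals[:, 1].mean()),
            "n_epochs": int(vals.shape[0]),
        }
    acts = out["per_activity"]
    out["mean_rmse"] = float(np.mean([a["rmse"] for a in acts.values()]))
    out["mean_corr"] = float(np.mean([a["corr"] for a in acts.values()]))
    return out


def plot_confusion(report: ClassificationReport, path) -> None:
    """Render the confusion matrix to an image file (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(report.confusion, cmap="Blues")
    ax.set_xticks(range(len(report.label_names)), report.label_names,
                  rotation=45, ha="right")
    ax.set_yticks(range(len(report.label_names)), report.label_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(report.confusion.shape[0]):
        for j in range(report.confusion.shape[1]):
            ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
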