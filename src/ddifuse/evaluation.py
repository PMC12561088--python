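"""Metric suite and misclassification analysis.

Accuracy plus macro-averaged precision/recall/F1 and one-vs-rest
AUROC/AUPR, all as unweighted means over classes present in the test set,
and the misclassification summary: per-class test counts, test-set share,
misclassified counts, and each class's share of all misclassified samples
(summing to 100% whenever any errors exist), with a top-k error heatmap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .pairs import ClassCatalog


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auroc: float
    macro_aupr: float
    per_class_accuracy: np.ndarray
    classes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_auroc": self.macro_auroc,
            "macro_aupr": self.macro_aupr,
        }


@dataclass
class ConfusionSummary:
    matrix: np.ndarray  # n_classes x n_classes counts, rows = true class
    table: pd.DataFrame  # per-class test_count / test_ratio_pct / miscls_count / miscls_ratio_pct

    def top_k(self, k: int) -> pd.DataFrame:
        return self.table.sort_values(
            "miscls_ratio_pct", ascending=False, kind="stable"
        ).head(k)


def compute_metrics(
    y_true: np.ndarray, proba: np.ndarray, n_classes: int | None = None
) -> MetricsReport:
    """Full metric suite from true labels and a row-stochastic score matrix.

    Macro averages run over classes present in the test set; classes absent
    from it are excluded with a warning (their one-vs-rest curves are
    undefined). Classes never predicted contribute precision 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or len(y_true) != len(proba):
        raise ValueError("labels and probability matrix are misaligned")
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    n_classes = n_classes or proba.shape[1]
    y_pred = np.argmax(proba, axis=1)
    present = np.unique(y_true)
    absent = sorted(set(range(n_classes)) - set(present.tolist()))
    if absent:
        warnings.warn(
            f"{len(absent)} classes absent from the test set are excluded "
            f"from macro averages: {absent[:10]}{'...' if len(absent) > 10 else ''}",
            stacklevel=2,
        )
    accuracy = float(np.mean(y_pred == y_true))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="macro", zero_division=0
    )
    aurocs, auprs = [], []
    for c in present:
        pos = y_true == c
        if pos.all():  # no negatives: curve undefined
            continue
        aurocs.append(roc_auc_score(pos, proba[:, c]))
        auprs.append(average_precision_score(pos, proba[:, c]))
    per_class_acc = np.array(
        [float(np.mean(y_pred[y_true == c] == c)) for c in present]
    )
    return MetricsReport(
        accuracy=accuracy,
        macro_precision=float(prec),
        macro_recall=float(rec),
        macro_f1=float(f1),
        macro_auroc=float(np.mean(aurocs)) if aurocs else float("nan"),
        macro_aupr=float(np.mean(auprs)) if auprs else float("nan"),
        per_class_accuracy=per_class_acc,
        classes=present,
    )


def misclassification_table(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    catalog: ClassCatalog | None = None,
    n_classes: int | None = None,
) -> ConfusionSummary:
    """Per-class misclassification summary.

    ``test_ratio_pct`` is the class's share of the test set;
    ``miscls_ratio_pct`` is its share of all misclassified samples, so the
    column sums to 100 whenever any errors exist (0 with a notice
    otherwise).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("labels are misaligned")
    if n_classes is None:
        n_classes = catalog.n_classes if catalog else int(max(y_true.max(), y_pred.max())) + 1
    matrix = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(matrix, (y_true, y_pred), 1)
    test_counts = matrix.sum(axis=1)
    total = test_counts.sum()
    miscls_counts = test_counts - np.diag(matrix)
    total_miscls = int(miscls_counts.sum())
    if total_miscls == 0:
        warnings.warn("no misclassifications; ratio column reported as 0", stacklevel=2)
        miscls_ratio = np.zeros(n_classes)
    else:
        miscls_ratio = 100.0 * miscls_counts / total_miscls
    table = pd.DataFrame(
        {
            "class_id": np.arange(n_classes),
            "description": [
                catalog.descriptions.get(c, f"class {c}") if catalog else f"class {c}"
                for c in range(n_classes)
            ],
            "test_count": test_counts,
            "test_ratio_pct": 100.0 * test_counts / total if total else 0.0,
            "miscls_count": miscls_counts,
            "miscls_ratio_pct": miscls_ratio,
        }
    )
    return ConfusionSummary(matrix=matrix, table=table)


def error_heatmap(summary: ConfusionSummary, top_k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Normalized top-k error matrix.

    Restricts the confusion matrix to the ``top_k`` classes ranked by their
    share of misclassified samples, divides off-diagonal cells by the total
    misclassified count, and masks the diagonal with NaN. Returns
    (matrix, class_ids).
    """
    if top_k > summary.matrix.shape[0]:
        raise ValueError("top_k exceeds the number of classes")
    order = summary.top_k(top_k)["class_id"].to_numpy()
    total_miscls = int(summary.table["miscls_count"].sum())
    sub = summary.matrix[np.ix_(order, order)].astype(float)
    if total_miscls > 0:
        sub = sub / total_miscls
    np.fill_diagonal(sub, np.nan)
    return sub, order


def plot_error_heatmap(summary: ConfusionSummary, top_k: int = 10, out_path=None):
    """Render the top-k error heatmap (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid, classes = error_heatmap(summary, top_k)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(grid, cmap="Reds")
    ax.set_xticks(range(len(classes)), classes)
    ax.set_yticks(range(len(classes)), classes)
    ax.set_xlabel("predicted type")
    ax.set_ylabel("true type")
    fig.colorbar(im, ax=ax, label="share of all misclassified samples")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
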