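"""Multiclass metrics and the hyperparameter sweep harness.

Scalar metrics for the 5-grade problem are macro one-vs-rest averages:
each class is scored against the rest (sensitivity = recall, specificity
= TN / (TN + FP), precision, F1) and the per-class values are averaged
unweighted.  Classes with a zero denominator contribute 0 and are listed
in ``MetricsReport.flagged_classes``.  AUC is the macro one-vs-rest
ranking AUC (trapezoidal, mid-rank ties).

The sweep harness retrains the CNN over a grid of activations x epochs x
learning rates x batch sizes x seeds, records one row per cell, and
pivots the long table into the familiar activation-by-grid-value layout.
Failed (diverged) runs are flagged rows, never crashes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score

from .model import DivergenceError, FundusCNNClassifier
from .nn import softmax_xent

__all__ = ["MetricsReport", "SweepGrid", "compute_metrics", "sweep",
           "render_table"]


@dataclass(frozen=True)
class MetricsReport:
    """Macro one-vs-rest metric bundle for an n-class evaluation."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float
    loss: float
    confusion: np.ndarray
    flagged_classes: tuple[int, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("accuracy", "sensitivity", "specificity", "precision",
                 "f1", "auc", "loss")}


def compute_metrics(true_labels, predicted_probabilities,
                    n_classes: int = 5) -> MetricsReport:
    """Compute accuracy, macro OvR sensitivity/specificity/precision/F1,
    macro OvR AUC, and mean cross-entropy loss from probability rows.

    Per-class values with a zero denominator (e.g. a class absent from
    the truth) contribute 0 to the macro average and the class index is
    recorded in ``flagged_classes``.
    """
    y = np.asarray(true_labels)
    proba = np.asarray(predicted_probabilities, dtype=float)
    if y.ndim != 1 or proba.ndim != 2 or len(y) != len(proba):
        raise ValueError(
            f"need n labels and an n x k probability matrix; got "
            f"{y.shape} and {proba.shape}"
        )
    if np.any((y < 0) | (y >= n_classes)):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    pred = proba.argmax(axis=1)
    labels = np.arange(n_classes)
    cm = confusion_matrix(y, pred, labels=labels)
    n = len(y)
    accuracy = float(np.trace(cm) / n)

    sens, spec, prec, f1s, aucs = [], [], [], [], []
    flagged: set[int] = set()
    for c in labels:
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = n - tp - fn - fp

        def _rate(num, den, c=c):
            if den == 0:
                flagged.add(int(c))
                return 0.0
            return num / den

        se = _rate(tp, tp + fn)
        sp = _rate(tn, tn + fp)
        pr = _rate(tp, tp + fp)
        f1 = _rate(2 * pr * se, pr + se) if (pr + se) > 0 else _rate(0, 0)
        sens.append(se)
        spec.append(sp)
        prec.append(pr)
        f1s.append(f1)
        binary = (y == c).astype(int)
        if binary.min() == binary.max():  # class absent or universal
            flagged.add(int(c))
            aucs.append(0.0)
        else:
            aucs.append(float(roc_auc_score(binary, proba[:, c])))

    logits = np.log(np.clip(proba, 1e-12, None))
    loss, _ = softmax_xent(logits, y)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(spec)),
        precision=float(np.mean(prec)),
        f1=float(np.mean(f1s)),
        auc=float(np.mean(aucs)),
        loss=float(loss),
        confusion=cm,
        flagged_classes=tuple(sorted(flagged)),
    )


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian sweep: activations x epochs x learning rates x batch
    sizes, replicated over seeds.  Defaults are desk-scale."""

    activations: tuple[str, ...] = ("proposed", "relu", "sigmoid")
    epochs_grid: tuple[int, ...] = (30,)
    lr_grid: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    batch_grid: tuple[int, ...] = (32,)
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self):
        from .activations import get_activation

        if not (self.activations and self.epochs_grid and self.lr_grid
                and self.batch_grid and self.seeds):
            raise ValueError("all sweep grids must be non-empty")
        for name in self.activations:
            get_activation(name)


def sweep(grid: SweepGrid, X_train, y_train, X_test, y_test,
          base_params: dict | None = None) -> pd.DataFrame:
    """Run the full grid; one row per (activation, epochs, lr, batch, seed).

    Columns: the grid coordinates plus final ``test_accuracy``,
    ``test_loss``, ``train_accuracy`` and a ``failed`` flag (True when
    training diverged; metric columns are NaN for such rows).
    """
    base_params = dict(base_params or {})
    rows = []
    for act, ep, lr, bs, seed in product(
        grid.activations, grid.epochs_grid, grid.lr_grid,
        grid.batch_grid, grid.seeds,
    ):
        clf = FundusCNNClassifier(
            activation=act, epochs=ep, learning_rate=lr, batch_size=bs,
            random_state=seed, **base_params,
        )
        row = {"activation": act, "epochs": ep, "lr": lr,
               "batch_size": bs, "seed": seed, "failed": False}
        try:
            clf.fit(X_train, y_train)
            report = compute_metrics(
                np.asarray(y_test), clf.predict_proba(X_test),
                n_classes=clf.n_classes,
            )
            row.update(
                test_accuracy=report.accuracy, test_loss=report.loss,
                train_accuracy=float(clf.history_["accuracy"].iloc[-1]),
            )
        except DivergenceError:
            row.update(test_accuracy=np.nan, test_loss=np.nan,
                       train_accuracy=np.nan, failed=True)
        rows.append(row)
    return pd.DataFrame.from_records(rows)


_PIVOTS = {"epochs": "epochs", "lr": "lr", "batch": "batch_size"}


def render_table(results: pd.DataFrame, pivot: str = "epochs"
                 ) -> tuple[pd.DataFrame, str]:
    """Pivot sweep results into an activation x grid-value accuracy grid.

    Cells are mean test accuracy over seeds, rounded (half-even) to two
    decimals.  Returns the pivoted DataFrame and its Markdown rendering.
    """
    if pivot not in _PIVOTS:
        raise ValueError(f"pivot must be one of {sorted(_PIVOTS)}")
    if results.empty:
        raise ValueError("results table is empty")
    col = _PIVOTS[pivot]
    table = (
        results.pivot_table(index="activation", columns=col,
                            values="test_accuracy", aggfunc="mean")
        .round(2)
    )
    table = table.reindex(pd.unique(results["activation"]))
    md_lines = ["| activation | " + " | ".join(str(c) for c in table.columns)
                + " |",
                "|" + "---|" * (len(table.columns) + 1)]
    for name, row in table.iterrows():
        cells = " | ".join(
            "—" if np.isnan(v) else f"{v:.2f}" for v in row.to_numpy()
        )
        md_lines.append(f"| {name} | {cells} |")
    return table, "\n".join(md_lines)
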