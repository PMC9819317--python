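"""Metrics and sweep harness: macro one-vs-rest algebra, grid mechanics."""

import numpy as np
import pandas as pd
import pytest

from fundusdr.evaluation import (
    MetricsReport,
    SweepGrid,
    compute_metrics,
    render_table,
    sweep,
)


def onehot(labels, k=5, hi=0.9):
    """Probability rows peaked on the given labels."""
    p = np.full((len(labels), k), (1 - hi) / (k - 1))
    p[np.arange(len(labels)), labels] = hi
    return p


def macro_ovr_oracle(cm: np.ndarray):
    """Scalar per-class one-vs-rest oracle for a confusion matrix."""
    n = cm.sum()
    k = cm.shape[0]
    sens, spec, prec, f1 = [], [], [], []
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = n - tp - fn - fp
        se = tp / (tp + fn) if tp + fn else 0.0
        sp = tn / (tn + fp) if tn + fp else 0.0
        pr = tp / (tp + fp) if tp + fp else 0.0
        f = 2 * pr * se / (pr + se) if pr + se else 0.0
        sens.append(se), spec.append(sp), prec.append(pr), f1.append(f)
    return map(float, (np.mean(sens), np.mean(spec), np.mean(prec),
                       np.mean(f1)))


def labels_from_confusion(cm, rng):
    """Build a (y_true, proba) pair whose confusion matrix equals cm."""
    ys, preds = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ys += [i] * cm[i, j]
            preds += [j] * cm[i, j]
    order = rng.permutation(len(ys))
    ys = np.array(ys)[order]
    preds = np.array(preds)[order]
    return ys, onehot(preds)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 4, 2, 1])
        rep = compute_metrics(y, onehot(y))
        assert rep.accuracy == rep.sensitivity == rep.precision == rep.f1 == 1.0
        assert rep.auc == 1.0
        assert rep.confusion.sum() == len(y)

    def test_binary_collapsed_auc_is_one(self):
        y = np.array([1, 1, 0, 0])
        proba = np.zeros((4, 2))
        proba[:, 1] = [0.9, 0.8, 0.4, 0.1]
        proba[:, 0] = 1 - proba[:, 1]
        rep = compute_metrics(y, proba, n_classes=2)
        assert rep.auc == 1.0  # perfectly separated rankings
        assert rep.flagged_classes == ()

    def test_macro_metrics_match_scalar_oracle(self, rng):
        for _ in range(10):
            cm = rng.integers(0, 12, size=(5, 5))
            if cm.sum() == 0:
                continue
            y, proba = labels_from_confusion(cm, rng)
            rep = compute_metrics(y, proba)
            se, sp, pr, f1 = macro_ovr_oracle(rep.confusion)
            assert rep.sensitivity == pytest.approx(se, abs=1e-12)
            assert rep.specificity == pytest.approx(sp, abs=1e-12)
            assert rep.precision == pytest.approx(pr, abs=1e-12)
            assert rep.f1 == pytest.approx(f1, abs=1e-12)
            assert rep.accuracy == pytest.approx(
                np.trace(rep.confusion) / rep.confusion.sum(), abs=1e-12
            )

    def test_confusion_sums_to_n_and_rates_in_unit_interval(self, rng):
        y = rng.integers(0, 5, size=60)
        proba = rng.dirichlet(np.ones(5), size=60)
        rep = compute_metrics(y, proba)
        assert rep.confusion.sum() == 60
        for v in rep.as_dict().values():
            assert v >= 0.0
        for k in ("accuracy", "sensitivity", "specificity", "precision",
                  "f1", "auc"):
            assert 0.0 <= getattr(rep, k) <= 1.0

    def test_auc_invariant_under_monotone_transform(self, rng):
        # ranking AUC depends only on the per-class score ordering
        y = rng.integers(0, 5, size=80)
        proba = rng.dirichlet(np.ones(5), size=80)
        rep1 = compute_metrics(y, proba)
        for warp in (lambda s: np.tanh(2.0 * s), lambda s: s**3,
                     lambda s: np.expm1(s)):
            rep2 = compute_metrics(y, warp(proba))
            assert rep2.auc == pytest.approx(rep1.auc, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            compute_metrics(np.array([0, 1]), np.ones((3, 5)) / 5)

    def test_absent_class_flagged_and_contributes_zero(self):
        y = np.array([0, 0, 1, 1])  # classes 2..4 absent
        rep = compute_metrics(y, onehot(y))
        assert set(rep.flagged_classes) >= {2, 3, 4}
        assert rep.sensitivity == pytest.approx(2 / 5, abs=1e-12)


@pytest.fixture(scope="module")
def tiny_sweep(small_dataset):
    grid = SweepGrid(
        activations=("proposed", "relu"), epochs_grid=(2,),
        lr_grid=(1e-2, 1e-3), batch_grid=(32,), seeds=(0, 1),
    )
    d = small_dataset
    return grid, sweep(grid, d["X_train"][:40], d["y_train"][:40],
                       d["X_test"][:10], d["y_test"][:10])


class TestSweep:
    def test_cartesian_row_count(self, tiny_sweep):
        grid, res = tiny_sweep
        assert len(res) == 2 * 1 * 2 * 1 * 2
        assert not res["failed"].any()

    def test_rerun_identical(self, tiny_sweep, small_dataset):
        grid, res = tiny_sweep
        d = small_dataset
        res2 = sweep(grid, d["X_train"][:40], d["y_train"][:40],
                     d["X_test"][:10], d["y_test"][:10])
        pd.testing.assert_frame_equal(res, res2)

    def test_diverged_cell_flagged_not_crash(self, small_dataset):
        grid = SweepGrid(activations=("relu",), epochs_grid=(3,),
                         lr_grid=(1e3,), batch_grid=(32,), seeds=(0,))
        d = small_dataset
        res = sweep(grid, d["X_train"][:40], d["y_train"][:40],
                    d["X_test"][:10], d["y_test"][:10],
                    base_params={"lr_schedule": "constant",
                                 "warmup_epochs": 0,
                                 "max_grad_norm": 1e9})
        assert res["failed"].iloc[0]
        assert np.isnan(res["test_accuracy"].iloc[0])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            SweepGrid(activations=())
        with pytest.raises(KeyError):
            SweepGrid(activations=("nope",))


class TestRenderTable:
    def test_pivot_shape_and_aggregation(self, rng):
        rows = []
        for act in ("proposed", "relu"):
            for ep in (10, 20, 30):
                for seed in (0, 1):
                    rows.append({"activation": act, "epochs": ep, "lr": 1e-2,
                                 "batch_size": 32, "seed": seed,
                                 "test_accuracy": rng.uniform(0.5, 1.0),
                                 "test_loss": 0.3, "train_accuracy": 0.9,
                                 "failed": False})
        df = pd.DataFrame(rows)
        table, md = render_table(df, pivot="epochs")
        assert table.shape == (2, 3)
        manual = df[(df.activation == "relu") & (df.epochs == 20)][
            "test_accuracy"].mean()
        assert table.loc["relu", 20] == pytest.approx(round(manual, 2))
        assert md.startswith("| activation |")

    def test_round_half_even_to_two_decimals(self):
        df = pd.DataFrame([{"activation": "a", "epochs": 1, "lr": 1,
                            "batch_size": 1, "seed": 0,
                            "test_accuracy": 0.9649, "test_loss": 0,
                            "train_accuracy": 1, "failed": False}])
        table, md = render_table(df, pivot="epochs")
        assert table.loc["a", 1] == 0.96
        assert "0.96" in md

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            render_table(pd.DataFrame(), pivot="epochs")
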