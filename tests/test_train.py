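"""Splitting, loss, early stopping, grid search and metric formulas."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ppgqc.architectures import ModelConfig, build_model
from ppgqc.synthetic import generate_dataset
from ppgqc.train import (
    ConfusionCounts,
    EarlyStopping,
    TrainConfig,
    bce_loss,
    compute_metrics,
    confusion_counts,
    grid_search,
    roc_auc,
    roc_points,
    stratified_split,
    stratified_split_indices,
    train,
)


def pairwise_auc(y, scores):
    """O(n^2) Mann-Whitney oracle: P(random positive outscores random
    negative), ties counted half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestStratifiedSplit:
    def test_proportion_arithmetic(self):
        y = np.array([1] * 60 + [0] * 40)
        tr, va, te = stratified_split_indices(y, (0.4, 0.3, 0.3), seed=0)
        assert (y[tr] == 1).sum() == 24 and (y[tr] == 0).sum() == 16
        assert len(va) == 30 and len(te) == 30

    def test_deterministic(self):
        y = np.array([0, 1] * 30)
        a = stratified_split_indices(y, seed=3)
        b = stratified_split_indices(y, seed=3)
        for x, z in zip(a, b):
            np.testing.assert_array_equal(x, z)

    def test_disjoint_and_exhaustive_on_random_datasets(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 120))
            y = rng.integers(0, 2, size=n)
            if min((y == 0).sum(), (y == 1).sum()) < 3:
                continue
            tr, va, te = stratified_split_indices(y, seed=int(rng.integers(1000)))
            union = np.concatenate([tr, va, te])
            assert len(union) == n
            assert len(np.unique(union)) == n

    def test_per_class_proportions_within_one_sample(self):
        y = np.array([1] * 55 + [0] * 45)
        tr, va, te = stratified_split_indices(y, (0.4, 0.3, 0.3), seed=1)
        for subset, frac in ((tr, 0.4), (va, 0.3), (te, 0.3)):
            for cls, total in ((1, 55), (0, 45)):
                got = (y[subset] == cls).sum()
                assert abs(got - frac * total) <= 1.0

    def test_small_class_rejected(self):
        y = np.array([1, 1, 1, 1, 0, 0])
        with pytest.raises(ValueError, match="class"):
            stratified_split_indices(y)

    def test_dataset_level_split(self):
        ds = generate_dataset(12, 6, 6, seed=0, duration_s=1.0, fs=64.0)
        tr, va, te = stratified_split(ds, seed=0)
        assert len(tr) + len(va) + len(te) == 24
        ids = [s.id for part in (tr, va, te) for s in part.signals]
        assert len(set(ids)) == 24


class TestBCE:
    def test_perfect_prediction_limit(self):
        assert bce_loss([1.0], [1.0 - 1e-7]) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_half_gives_ln2(self):
        y = np.array([1, 0, 1, 1, 0])
        assert bce_loss(y, np.full(5, 0.5)) == pytest.approx(np.log(2), abs=1e-12)

    def test_two_sample_closed_form(self):
        # -(log 0.8 + log 0.6) / 2
        expected = -(np.log(0.8) + np.log(0.6)) / 2  # = 0.3669846...
        assert bce_loss([1, 0], [0.8, 0.4]) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([1, 0], [0.5])


class TestEarlyStopping:
    def test_constant_validation_loss_stops_after_patience(self):
        """Improvements at epochs 1-3, constant thereafter: with patience 50
        the run stops at epoch 53 and the best epoch is 3."""
        stopper = EarlyStopping(patience=50)
        losses = [1.0, 0.9, 0.8] + [0.8] * 100
        stopped_at = None
        for epoch, loss in enumerate(losses, 1):
            stopper.update(loss)
            if stopper.stop:
                stopped_at = epoch
                break
        assert stopped_at == 53
        assert stopper.best_epoch == 3
        assert stopper.best_loss == 0.8

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopping(patience=50)
        for epoch in range(1, 201):
            stopper.update(1.0 / epoch)
            assert not stopper.stop
        assert stopper.best_epoch == 200

    def test_tie_does_not_reset_patience(self):
        stopper = EarlyStopping(patience=3)
        for loss in [1.0, 0.5, 0.5, 0.5]:
            stopper.update(loss)
        assert not stopper.stop  # only two ties so far
        stopper.update(0.5)
        assert stopper.stop


@pytest.fixture(scope="module")
def tiny_task():
    """A linearly separable toy problem: mean level codes the class."""
    rng = np.random.default_rng(0)
    n, length = 60, 32
    y = np.tile([0, 1], n // 2)
    x = rng.normal(0, 0.1, size=(n, length)) + y[:, None] * 0.8 + 0.1
    return (x[:40], y[:40]), (x[40:], y[40:])


class TestTrainLoop:
    def test_checkpoint_attains_minimum_validation_loss(self, tiny_task):
        train_set, val_set = tiny_task
        cfg = ModelConfig.cnn_mlp(input_length=32, conv_kernel=3, conv_channels=2,
                                  pool_size=2, ff_dims=(8,))
        model = build_model(cfg, np.random.default_rng(0))
        model, history = train(model, train_set, val_set,
                               TrainConfig(max_epochs=15, patience=15, seed=0))
        assert history["best_val_loss"] == min(history["val_loss"])
        assert history["best_epoch"] == int(np.argmin(history["val_loss"])) + 1
        # the returned weights reproduce the recorded best loss
        from ppgqc.train import _forward_loss

        assert _forward_loss(model, *val_set) == pytest.approx(
            history["best_val_loss"], abs=1e-9
        )

    def test_reproducible_histories(self, tiny_task):
        train_set, val_set = tiny_task
        cfg = ModelConfig.cnn_mlp(input_length=32, conv_kernel=3, conv_channels=2,
                                  pool_size=2, ff_dims=(8,))
        histories = []
        for _ in range(2):
            model = build_model(cfg, np.random.default_rng(4))
            _, h = train(model, train_set, val_set,
                         TrainConfig(max_epochs=5, patience=5, seed=4))
            histories.append(h)
        assert histories[0]["val_loss"] == histories[1]["val_loss"]
        assert histories[0]["train_loss"] == histories[1]["train_loss"]

    def test_empty_split_rejected(self, tiny_task):
        train_set, val_set = tiny_task
        cfg = ModelConfig.cnn_mlp(input_length=32, conv_kernel=3, conv_channels=2,
                                  pool_size=2, ff_dims=(8,))
        model = build_model(cfg, np.random.default_rng(0))
        empty = (np.empty((0, 32)), np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            train(model, empty, val_set, TrainConfig())


class TestGridSearch:
    def test_trains_every_configuration_and_returns_argmax(self, tiny_task):
        space = [
            ModelConfig.cnn_mlp(input_length=32, conv_kernel=k, conv_channels=2,
                                pool_size=2, ff_dims=(8,))
            for k in (3, 5, 7)
        ]
        best, leaderboard = grid_search(
            space, tiny_task, TrainConfig(max_epochs=4, patience=4, seed=0)
        )
        assert len(leaderboard) == 3
        aucs = [e["val_auc"] for e in leaderboard]
        assert all(a is not None for a in aucs)
        assert best in space
        assert max(aucs) == next(
            e["val_auc"] for e in leaderboard if e["config"] is best
        )

    def test_failed_configuration_is_recorded_not_fatal(self, tiny_task):
        bad = ModelConfig.cnn_mlp(input_length=32, conv_kernel=31, conv_channels=2,
                                  pool_size=32, ff_dims=(8,))  # collapses to length 0
        good = ModelConfig.cnn_mlp(input_length=32, conv_kernel=3, conv_channels=2,
                                   pool_size=2, ff_dims=(8,))
        best, leaderboard = grid_search(
            [bad, good], tiny_task, TrainConfig(max_epochs=2, patience=2, seed=0)
        )
        assert best is good
        assert "error" in leaderboard[0]


class TestMetrics:
    def test_hand_tally_example(self):
        counts = confusion_counts(
            np.array([1, 1, 0, 0]), np.array([0.9, 0.2, 0.8, 0.1]), 0.5
        )
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 1, 1, 1)
        assert counts.total == 4

    def test_counts_conserve_sample_size(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 50))
            y = rng.integers(0, 2, n)
            s = rng.uniform(0, 1, n)
            assert confusion_counts(y, s, 0.5).total == n

    def test_worked_confusion_matrix(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=4))
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(0.666667, abs=1e-6)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_convention(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = compute_metrics(ConfusionCounts(tp=0, fp=3, fn=0, tn=2))
        assert m.precision == 0.0 and m.f1 == 0.0

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(30):
            c = ConfusionCounts(*[int(v) for v in rng.integers(1, 20, 4)])
            m = compute_metrics(c)
            assert min(m.precision, m.recall) <= m.f1 <= max(m.precision, m.recall)


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1])) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc(np.array([1, 0, 1, 0]), np.full(4, 0.5)) == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
            assert roc_auc(y, s) == pytest.approx(pairwise_auc(y, s), abs=1e-12)

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, 200)
        s = rng.uniform(0, 1, 200)
        assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 100)
        s = rng.uniform(0.01, 0.99, 100)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, s**3), abs=1e-12)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, np.log(s)), abs=1e-12)

    def test_roc_points_monotone(self, rng):
        y = rng.integers(0, 2, 50)
        s = rng.uniform(0, 1, 50)
        pts = roc_points(y, s)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)
        np.testing.assert_array_equal(pts[0], [0, 0])
        np.testing.assert_array_equal(pts[-1], [1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(5), np.linspace(0, 1, 5))
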