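"""Architecture arithmetic, loss, schedule, splits, and evaluation metrics."""

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix, precision_score, recall_score

from seedspec import (
    ModelSpec,
    SpectraTable,
    TrainConfig,
    build_model,
    count_macs,
    count_params,
    cross_entropy,
    evaluate,
    lr_at,
    predict,
    reshape_geometry,
    stratified_split,
    train,
    widths_for,
)
from seedspec.model import _macro_precision_recall


class TestArchitectureArithmetic:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (1.0, (16, 32, 64, 32, 16)),
            (0.75, (12, 24, 48, 24, 12)),
            (1.25, (20, 40, 80, 40, 20)),
        ],
    )
    def test_depth_scaled_widths(self, d, expected):
        assert widths_for(d) == expected

    @pytest.mark.parametrize("D,geom", [(192, (3, 8, 8)), (768, (3, 16, 16)), (3072, (3, 32, 32))])
    def test_reshape_geometry(self, D, geom):
        assert reshape_geometry(D) == geom

    @pytest.mark.parametrize("bad", [100, 3 * 9 * 9, 50])
    def test_invalid_map_dim_raises(self, bad):
        with pytest.raises(ValueError):
            reshape_geometry(bad)

    @pytest.mark.parametrize(
        "d,D,expected",
        [
            (1.0, 768, 90_567),
            (1.0, 192, 57_735),
            (0.75, 768, 70_231),
        ],
    )
    def test_param_count_closed_form(self, d, D, expected):
        spec = ModelSpec(depth_factor=d, map_dim=D, n_input_bands=56, n_classes=7)
        assert count_params(spec) == expected

    def test_mac_count_closed_form(self):
        spec = ModelSpec(1.0, 768, 56, 7)
        assert count_macs(spec) == 3_987_568

    def test_conv_macs_scale_with_spatial_area(self):
        def conv_macs(D):
            spec = ModelSpec(1.0, D, 56, 7)
            return count_macs(spec) - 56 * D - 16 * 7

        assert conv_macs(768) == 4 * conv_macs(192)

    def test_macs_at_least_weight_count(self):
        for d in (0.75, 1.0, 1.25):
            for D in (192, 768, 3072):
                spec = ModelSpec(d, D, 56, 7)
                n_bias = spec.map_dim + sum(spec.widths) + spec.n_classes
                assert count_macs(spec) >= count_params(spec) - n_bias

    def test_formula_matches_built_network(self):
        spec = ModelSpec(1.25, 192, 30, 5)
        assert build_model(spec, seed=0).n_params == count_params(spec)


class TestLossAndSchedule:
    def test_uniform_prediction_loss_is_log_q(self):
        probs = np.full((4, 7), 1 / 7)
        assert cross_entropy(probs, np.array([0, 3, 5, 6])) == pytest.approx(np.log(7), abs=1e-9)

    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert cross_entropy(probs, np.array([0, 1, 2])) == pytest.approx(0.0, abs=1e-12)

    def test_half_probability(self):
        probs = np.array([[0.5, 0.25, 0.25]])
        assert cross_entropy(probs, np.array([0])) == pytest.approx(np.log(2), abs=1e-9)

    def test_zero_probability_clamped_with_warning(self):
        probs = np.array([[0.0, 1.0]])
        with pytest.warns(UserWarning, match="clamp"):
            loss = cross_entropy(probs, np.array([0]))
        assert loss == pytest.approx(-np.log(1e-12))

    def test_initial_learning_rate(self):
        assert lr_at(0, TrainConfig()) == pytest.approx(0.01)

    def test_final_epoch_learning_rate(self):
        cfg = TrainConfig(epochs=10_000)
        assert lr_at(9_999, cfg) == pytest.approx(0.01 * (1 / 10_000) ** 0.9)

    def test_schedule_strictly_decreasing(self):
        cfg = TrainConfig(epochs=50)
        lrs = [lr_at(e, cfg) for e in range(50)]
        assert all(a > b for a, b in zip(lrs, lrs[1:]))


class TestStratifiedSplit:
    def test_balanced_seven_class_design(self):
        labels = np.repeat(np.arange(7), 105)
        folds = stratified_split(labels, 3, seed=0)
        for f in range(3):
            test = labels[folds == f]
            assert test.size == 245
            assert labels[folds != f].size == 490
            np.testing.assert_array_equal(np.bincount(test), [35] * 7)
            np.testing.assert_array_equal(np.bincount(labels[folds != f]), [70] * 7)

    def test_round_robin_two_classes(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        folds = stratified_split(labels, 3, seed=1)
        for f in range(3):
            sub = labels[folds == f]
            assert sub.size == 2 and set(sub) == {0, 1}

    def test_single_fold_invalid(self):
        with pytest.raises(ValueError, match="folds"):
            stratified_split(np.array([0, 0, 1, 1]), 1)

    def test_class_smaller_than_folds_raises(self):
        with pytest.raises(ValueError, match="class"):
            stratified_split(np.array([0, 0, 0, 1]), 3)


def _tiny_table(rng, n=24, b=10, q=3):
    X = rng.normal(size=(n, b))
    y = np.arange(n) % q
    X[np.arange(n), y] += 3.0  # separable signal
    return SpectraTable(values=X, wavelengths=np.linspace(1000, 1090, b), labels=y)


class TestTraining:
    def test_feature_count_mismatch_raises(self, rng):
        t = _tiny_table(rng)
        model = build_model(ModelSpec(1.0, 12, n_input_bands=5, n_classes=3))
        with pytest.raises(ValueError, match="bands"):
            train(model, t)

    def test_zero_epoch_training_keeps_initialization(self, rng):
        t = _tiny_table(rng)
        spec = ModelSpec(1.0, 12, 10, 3)
        model = build_model(spec, seed=5)
        before = {k: v.copy() for k, v in model.params.items()}
        hist = train(model, t, TrainConfig(epochs=0))
        assert hist == []
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])

    def test_same_seed_identical_histories(self, rng):
        t = _tiny_table(rng)
        spec = ModelSpec(1.0, 12, 10, 3)
        cfg = TrainConfig(epochs=8, batch_size=8, seed=9)
        h1 = train(build_model(spec, seed=9), t, cfg)
        h2 = train(build_model(spec, seed=9), t, cfg)
        assert h1 == h2

    def test_loss_history_length_and_decrease(self, rng):
        t = _tiny_table(rng, n=60)
        spec = ModelSpec(1.0, 12, 10, 3)
        model = build_model(spec, seed=0)
        hist = train(model, t, TrainConfig(epochs=40, batch_size=16, seed=0))
        assert len(hist) == 40
        assert np.mean(hist[-5:]) < np.mean(hist[:5])

    def test_prediction_rows_on_simplex(self, rng):
        t = _tiny_table(rng)
        model = build_model(ModelSpec(1.0, 12, 10, 3), seed=1)
        pred = predict(model, t)
        assert np.all(pred.probs >= 0)
        np.testing.assert_allclose(pred.probs.sum(axis=1), 1.0, atol=1e-6)


def test_loss_decreases_for_all_nine_architectures(small_dataset):
    """Every (d, D) variant optimizes on class-structured spectra.

    Uses a subsample and short schedule; the property under test is
    that the first SGD epochs reduce the loss for each architecture.
    """
    from seedspec import preprocess

    table = preprocess(small_dataset.table)
    sub = table.take_rows(np.arange(0, table.n_samples, 2))
    for d in (0.75, 1.0, 1.25):
        for D in (192, 768, 3072):
            spec = ModelSpec(d, D, sub.n_bands, sub.n_classes)
            model = build_model(spec, seed=3)
            hist = train(model, sub, TrainConfig(epochs=25, batch_size=8, seed=3))
            assert np.mean(hist[-5:]) < np.mean(hist[:5]), (d, D)


class TestEvaluation:
    def test_hand_worked_confusion(self):
        conf = np.array([[2, 1], [0, 3]])
        prec, rec = _macro_precision_recall(conf)
        assert prec == pytest.approx((1.0 + 0.75) / 2)
        assert rec == pytest.approx((2 / 3 + 1.0) / 2)

    def test_perfect_predictor(self, rng):
        t = _tiny_table(rng, n=30)
        spec = ModelSpec(1.0, 12, 10, 3)
        model = build_model(spec, seed=0)
        train(model, t, TrainConfig(epochs=60, batch_size=8, seed=0))
        acc, prec, rec, conf = evaluate(model, t)
        if acc == 1.0:  # converged: diagonal confusion, perfect macro scores
            assert prec == rec == 1.0
            assert np.trace(conf) == 30

    def test_constant_predictor_macro_recall(self):
        conf = np.zeros((7, 7), dtype=int)
        conf[:, 0] = 10  # everything predicted as class 0
        with pytest.warns(UserWarning, match="never predicted"):
            prec, rec = _macro_precision_recall(conf)
        assert rec == pytest.approx(1 / 7)
        assert prec == pytest.approx((10 / 70) / 7)

    def test_metrics_match_sklearn(self, rng):
        """Independent oracle: sklearn's confusion/precision/recall."""
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        conf = np.zeros((4, 4), dtype=int)
        np.add.at(conf, (y_true, y_pred), 1)
        np.testing.assert_array_equal(conf, confusion_matrix(y_true, y_pred))
        prec, rec = _macro_precision_recall(conf)
        assert prec == pytest.approx(precision_score(y_true, y_pred, average="macro", zero_division=0))
        assert rec == pytest.approx(recall_score(y_true, y_pred, average="macro", zero_division=0))
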