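"""Prediction harness: scaling contracts, tiny CNN, calibration, evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score

from orgfate.morphometrics import FEATURE_NAMES
from orgfate.partitioning import SplitPlan, make_loeo_splits
from orgfate.prediction import (FeatureScaler, PredictionRun, TinyConvNet,
                                class_weights, compare_classifiers,
                                ensemble_predict, f1_by_bin_distance,
                                f1_over_time, morphology_cluster_targets,
                                normalized_auc, prepare_cnn_input,
                                temperature_calibrate,
                                train_feature_classifier)


def toy_features(n_exp=3, wells=8, loops=4, seed=0, signal=2.0):
    """Tabular fixture: two informative columns + noise, organoid labels."""
    rng = np.random.default_rng(seed)
    rows, labels = [], {}
    for e in range(n_exp):
        for w in range(wells):
            key = (f"E{e + 1:03d}", f"W{w:03d}")
            y = int(rng.random() < 0.5)
            labels[key] = y
            for loop in range(loops):
                feat = rng.normal(size=6)
                feat[0] += signal * y
                feat[1] -= signal * y
                rows.append([key[0], key[1], loop, *feat])
    df = pd.DataFrame(rows, columns=["experiment_id", "well_id", "loop",
                                     *[f"f{i}" for i in range(6)]])
    return df, pd.Series(labels)


class TestFeatureClassifier:
    def test_strong_signal_recovered_on_test_experiment(self):
        table, labels = toy_features(signal=5.0)
        split = make_loeo_splits(
            table[["experiment_id", "well_id"]].drop_duplicates(), seed=0)[0]
        run = train_feature_classifier(table, labels, split,
                                       LogisticRegression(C=100, max_iter=500))
        curve = f1_over_time(run, "test")
        assert curve["f1"].mean() > 0.9

    def test_scaler_fitted_on_training_rows_only(self):
        table, labels = toy_features()
        split = make_loeo_splits(
            table[["experiment_id", "well_id"]].drop_duplicates(), seed=0)[0]
        n_train_rows = sum(
            (e, w) in split.train_organoids
            for e, w in zip(table.experiment_id, table.well_id))
        scaler = FeatureScaler()
        x = table[[c for c in table if c.startswith("f")]].to_numpy()
        mask = [(e, w) in split.train_organoids
                for e, w in zip(table.experiment_id, table.well_id)]
        scaler.fit(x[np.array(mask)])
        assert scaler.fitted_on_ == n_train_rows
        z = scaler.transform(x[np.array(mask)])
        assert z.min() == pytest.approx(0.0) and z.max() == pytest.approx(1.0)

    def test_single_class_training_fold_rejected(self):
        table, labels = toy_features()
        labels[:] = 1
        split = make_loeo_splits(
            table[["experiment_id", "well_id"]].drop_duplicates(), seed=0)[0]
        with pytest.raises(ValueError, match="single class"):
            train_feature_classifier(table, labels, split,
                                     LogisticRegression())


class TestClassWeights:
    def test_inverse_frequency_formula(self):
        y = np.array([0] * 30 + [1] * 10)
        w = class_weights(y, np.array([0, 1]))
        # w_c = n / (K * n_c)
        assert w[0] == pytest.approx(40 / (2 * 30))
        assert w[1] == pytest.approx(40 / (2 * 10))

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            class_weights(np.array([0, 0]), np.array([0, 1]))


class TestPrepareCnnInput:
    def test_output_shape_is_contract(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 5, (400, 400))
        yy, xx = np.mgrid[0:400, 0:400]
        mask = (yy - 200) ** 2 + (xx - 180) ** 2 <= 90 ** 2
        crop, mcrop = prepare_cnn_input(img, mask)
        assert crop.shape == (224, 224) and mcrop.shape == (224, 224)

    def test_background_unchanged_by_organoid_only_normalisation(self):
        rng = np.random.default_rng(1)
        img = np.full((300, 300), 50.0)
        img += rng.normal(0, 1, img.shape)
        yy, xx = np.mgrid[0:300, 0:300]
        mask = (yy - 150) ** 2 + (xx - 150) ** 2 <= 60 ** 2
        img[mask] += 60.0
        crop, mcrop = prepare_cnn_input(img, mask, crop_px=200, out_px=100)
        # background stays on the [0, 1] scale; organoid pixels are z-scored
        assert crop[~mcrop].min() >= 0.0 and crop[~mcrop].max() <= 1.0
        assert abs(crop[mcrop].mean()) < 1e-6
        assert crop[mcrop].std() == pytest.approx(1.0, abs=1e-6)

    def test_crop_beyond_frame_padded_with_background(self):
        img = np.full((100, 100), 30.0)
        yy, xx = np.mgrid[0:100, 0:100]
        mask = (yy - 10) ** 2 + (xx - 10) ** 2 <= 9 ** 2
        img[mask] = 90.0
        crop, mcrop = prepare_cnn_input(img, mask, crop_px=80, out_px=80)
        assert crop.shape == (80, 80)
        assert mcrop.sum() == pytest.approx(mask.sum(), rel=0.1)

    def test_deterministic_without_augmentation(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(128, 128))
        yy, xx = np.mgrid[0:128, 0:128]
        mask = (yy - 64) ** 2 + (xx - 64) ** 2 <= 30 ** 2
        a, _ = prepare_cnn_input(img, mask, crop_px=96, out_px=64)
        b, _ = prepare_cnn_input(img, mask, crop_px=96, out_px=64)
        assert np.array_equal(a, b)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            prepare_cnn_input(np.zeros((64, 64)), np.zeros((64, 64), bool))


class TestTinyConvNet:
    def test_analytic_gradients_match_numeric(self):
        rng = np.random.default_rng(3)
        net = TinyConvNet(n_classes=2, pool_px=8, channels=(2, 3), seed=0)
        x = rng.normal(size=(4, 8, 8))
        y = np.array([0, 1, 0, 1])
        w = np.ones(2)
        _, grads = net._loss_grad(x, y, w)
        eps = 1e-6
        for name in ("w1", "b2", "wd", "bd"):
            p = net.params[name]
            flat_idx = [0, p.size // 2]
            for fi in flat_idx:
                orig = p.flat[fi]
                p.flat[fi] = orig + eps
                up, _ = net._loss_grad(x, y, w)
                p.flat[fi] = orig - eps
                down, _ = net._loss_grad(x, y, w)
                p.flat[fi] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name].flat[fi] == pytest.approx(
                    numeric, rel=1e-4, abs=1e-7), name

    def test_learns_separable_images(self):
        rng = np.random.default_rng(4)
        n = 80
        y = rng.integers(0, 2, n)
        x = rng.normal(0, 0.3, (n, 16, 16))
        xx = np.linspace(0, 2 * np.pi * 4, 16)
        stripe = np.sin(xx)[None, :] * np.ones((16, 1))
        x[y == 1] += stripe
        net = TinyConvNet(2, pool_px=16, channels=(4, 8), seed=0)
        w = class_weights(y[:60], np.array([0, 1]))
        net.fit(x[:60], y[:60], x[60:], y[60:], w, epochs=40, seed=0)
        pred = net.predict_logits(x[60:]).argmax(axis=1)
        assert (pred == y[60:]).mean() >= 0.9

    def test_lr_halved_on_plateau(self):
        # an (effectively) frozen net plateaus immediately: after `patience`
        # stale epochs the learning rate must halve
        rng = np.random.default_rng(5)
        x = rng.normal(size=(16, 8, 8))
        y = rng.integers(0, 2, 16)
        net = TinyConvNet(2, pool_px=8, channels=(2, 2), seed=0)
        net.fit(x, y, x, y, np.ones(2), epochs=20, lr=1e-9, patience=7, seed=0)
        lrs = [h["lr"] for h in net.history]
        assert min(lrs) < max(lrs)  # at least one halving on plateau
        assert lrs[0] == 1e-9 and min(lrs) <= 1e-9 / 2


class TestTemperature:
    @staticmethod
    def _softmax_labels(logits, rng):
        p = np.exp(logits - logits.max(1, keepdims=True))
        p /= p.sum(1, keepdims=True)
        return np.array([rng.choice(p.shape[1], p=pi) for pi in p])

    def test_calibrated_logits_recover_t_near_one(self):
        rng = np.random.default_rng(6)
        logits = rng.normal(0, 2, (4000, 3))
        y = self._softmax_labels(logits, rng)
        assert temperature_calibrate(logits, y) == pytest.approx(1.0, abs=0.05)

    def test_scaled_logits_recover_scale_factor(self):
        rng = np.random.default_rng(7)
        logits = rng.normal(0, 2, (4000, 3))
        y = self._softmax_labels(logits, rng)
        assert temperature_calibrate(logits * 3.0, y) == pytest.approx(
            3.0, rel=0.10)

    def test_argmax_unchanged_by_calibration(self):
        rng = np.random.default_rng(8)
        logits = rng.normal(size=(100, 4))
        t = temperature_calibrate(logits, rng.integers(0, 4, 100))
        assert np.array_equal(logits.argmax(1), (logits / t).argmax(1))

    def test_degenerate_logits_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            temperature_calibrate(np.ones((10, 3)), np.zeros(10, int))


def _mock_run(proba, y_true, loops=None, model_id="m", best_f1=1.0):
    classes = np.arange(proba.shape[1])
    n = len(y_true)
    df = pd.DataFrame({
        "experiment_id": ["E001"] * n,
        "well_id": [f"W{i:03d}" for i in range(n)],
        "loop": loops if loops is not None else [0] * n,
        "subset": ["test"] * n,
        "y_true": y_true,
        "y_pred": classes[proba.argmax(1)],
    })
    for j, c in enumerate(classes):
        df[f"p_{c}"] = proba[:, j]
    split = SplitPlan(0, "E001", frozenset({("E002", "W0")}),
                      frozenset({("E002", "W1")}), 0)
    run = PredictionRun("task", split, model_id, classes, df)
    run.best_validation_f1 = best_f1
    return run


class TestEnsemble:
    def test_degenerate_weights_reproduce_single_model(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 30)
        a = _mock_run(rng.dirichlet([1, 1], 30), y)
        b = _mock_run(rng.dirichlet([1, 1], 30), y)
        ens = ensemble_predict([a, b], weights=[1.0, 0.0])
        assert np.allclose(ens.proba(), a.proba())

    def test_equal_weights_average(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 30)
        a = _mock_run(rng.dirichlet([1, 1], 30), y)
        b = _mock_run(rng.dirichlet([1, 1], 30), y)
        ens = ensemble_predict([a, b], weights=[0.5, 0.5])
        assert np.allclose(ens.proba(), 0.5 * (a.proba() + b.proba()))

    def test_ensemble_f1_at_least_min_member(self):
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(11)
        for _ in range(20):
            y = rng.integers(0, 2, 60)
            noise_a, noise_b = rng.uniform(0.1, 0.6, 2)
            pa = np.eye(2)[y] * (1 - noise_a) + rng.dirichlet([1, 1], 60) * noise_a
            pb = np.eye(2)[y] * (1 - noise_b) + rng.dirichlet([1, 1], 60) * noise_b
            a = _mock_run(pa, y, best_f1=1 - noise_a)
            b = _mock_run(pb, y, best_f1=1 - noise_b)
            ens = ensemble_predict([a, b])
            scores = [f1_score(y, r.predictions["y_pred"], average="weighted")
                      for r in (a, b, ens)]
            assert scores[2] >= min(scores[:2]) - 1e-12

    def test_empty_run_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ensemble_predict([])


class TestF1Evaluation:
    def test_perfect_predictions_give_f1_one(self):
        y = np.array([0, 1, 0, 1])
        run = _mock_run(np.eye(2)[y], y, loops=[0, 0, 1, 1])
        curve = f1_over_time(run, "test")
        assert (curve["f1"] == 1.0).all()

    def test_constant_single_class_prediction_weighted_f1_one_third(self):
        # balanced binary truth, always predicting class 1:
        # class 1: P=0.5, R=1 -> F1=2/3; class 0: F1=0; weighted = 1/3
        y = np.array([0, 1] * 10)
        proba = np.tile([0.1, 0.9], (20, 1))
        run = _mock_run(proba, y)
        curve = f1_over_time(run, "test")
        assert curve["f1"].iloc[0] == pytest.approx(1 / 3)

    def test_matches_brute_force_confusion_f1(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 3, 200)
        proba = rng.dirichlet([1, 1, 1], 200)
        run = _mock_run(proba, y)
        got = f1_over_time(run, "test")["f1"].iloc[0]
        pred = proba.argmax(1)
        total = 0.0
        for c in range(3):
            tp = ((pred == c) & (y == c)).sum()
            fp = ((pred == c) & (y != c)).sum()
            fn = ((pred != c) & (y == c)).sum()
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            total += (y == c).mean() * f1
        assert got == pytest.approx(total, rel=1e-12)


class TestBinDistanceStratification:
    def test_strata_partition_all_samples(self):
        rng = np.random.default_rng(13)
        y = rng.integers(1, 4, 50)
        run = _mock_run(rng.dirichlet([1] * 4, 50), y)
        d = pd.Series(rng.uniform(0, 1, 50),
                      index=pd.MultiIndex.from_arrays(
                          [run.predictions.experiment_id,
                           run.predictions.well_id]))
        table = f1_by_bin_distance(run, d, n_strata=5)
        assert table["n"].sum() == 50

    def test_edge_concentrated_errors_give_decreasing_f1(self):
        n = 300
        rng = np.random.default_rng(14)
        y = rng.integers(0, 2, n)
        d_vals = rng.uniform(0, 1, n)
        pred = y.copy()
        flip = rng.random(n) < d_vals * 0.8  # errors pile up near the edge
        pred[flip] = 1 - pred[flip]
        proba = np.eye(2)[pred] * 0.9 + 0.05
        run = _mock_run(proba, y)
        d = pd.Series(d_vals, index=pd.MultiIndex.from_arrays(
            [run.predictions.experiment_id, run.predictions.well_id]))
        table = f1_by_bin_distance(run, d, n_strata=4)
        assert table["f1"].iloc[0] > table["f1"].iloc[-1]


class TestCompareClassifiers:
    @staticmethod
    def _curve(f1s, loops=None):
        return pd.DataFrame({"loop": loops or range(len(f1s)), "f1": f1s})

    def test_constant_curve_auc_is_value(self):
        assert normalized_auc(self._curve([0.7] * 9)) == pytest.approx(0.7)
        assert normalized_auc(
            self._curve([0.7] * 3, loops=[0, 5, 17])) == pytest.approx(0.7)

    def test_identical_methods_p_value_one(self):
        curves = {
            "a": {f"E{i}": self._curve([0.5, 0.6, 0.7]) for i in range(6)},
            "b": {f"E{i}": self._curve([0.5, 0.6, 0.7]) for i in range(6)},
        }
        table = compare_classifiers(curves)
        assert table["p_raw"].iloc[0] == 1.0

    def test_holm_adjustment_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests([0.01, 0.02, 0.04], alpha=0.05,
                                            method="holm")
        assert np.allclose(p_adj, [0.03, 0.04, 0.04])
        assert reject.all()

    def test_unpaired_experiments_dropped_with_warning(self):
        rng = np.random.default_rng(15)
        mk = lambda: self._curve(rng.uniform(0.4, 0.9, 5))  # noqa: E731
        curves = {
            "a": {f"E{i}": mk() for i in range(6)},
            "b": {f"E{i}": mk() for i in range(1, 7)},  # E0 / E6 unpaired
        }
        with pytest.warns(UserWarning, match="unpaired"):
            table = compare_classifiers(curves)
        assert table["n_experiments"].iloc[0] == 5


class TestMorphologyClusters:
    def test_four_separated_blobs_recovered(self):
        rng = np.random.default_rng(16)
        x, truth = [], []
        for c in range(4):
            x.append(rng.normal(size=(12, 165)) + c * 50.0)
            truth += [c] * 12
        table = pd.DataFrame(np.vstack(x), columns=FEATURE_NAMES)
        table.insert(0, "experiment_id", "E001")
        table.insert(1, "well_id", [f"W{i:03d}" for i in range(48)])
        table.insert(2, "loop", 99)
        labels = morphology_cluster_targets(table, seed=0)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_seeded_run_reproducible(self):
        rng = np.random.default_rng(17)
        table = pd.DataFrame(rng.normal(size=(40, 20)),
                             columns=[f"f{i}" for i in range(20)])
        table.insert(0, "experiment_id", "E001")
        table.insert(1, "well_id", [f"W{i:03d}" for i in range(40)])
        table.insert(2, "loop", 0)
        a = morphology_cluster_targets(table, seed=5)
        b = morphology_cluster_targets(table, seed=5)
        assert (a == b).all()

    def test_fewer_organoids_than_clusters_rejected(self):
        table = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)),
                             columns=[f"f{i}" for i in range(5)])
        table.insert(0, "experiment_id", "E001")
        table.insert(1, "well_id", list("abc"))
        table.insert(2, "loop", 0)
        with pytest.raises(ValueError, match="fewer organoids"):
            morphology_cluster_targets(table)
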