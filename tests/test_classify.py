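"""PCA reducer contracts, classifier backends, fusion, leakage protection."""

import numpy as np
import pytest

from m3 import classify
from m3.classify import FeatureTable, fit_classifier, fit_reducer, predict_scores, transform

RNG = np.random.default_rng(7)


def _table(X, y):
    return FeatureTable(X=np.asarray(X, float), y=np.asarray(y, int))


class TestReducer:
    def test_rank_one_data_needs_one_component(self):
        t = RNG.normal(size=20)
        direction = np.array([1.0, -2.0, 0.5, 3.0, 1.5])
        X = np.outer(t, direction)
        red = fit_reducer(_table(X, [0, 1] * 10), variance_target=0.95)
        assert red.n_components == 1
        assert red.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_axes_orthonormal_and_ratios_sorted(self):
        X = RNG.normal(size=(40, 12)) @ RNG.normal(size=(12, 12))
        red = fit_reducer(_table(X, [0, 1] * 20), variance_target=1.0)
        gram = red.components @ red.components.T
        np.testing.assert_allclose(gram, np.eye(red.n_components), atol=1e-8)
        ratios = red.explained_variance_ratio
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1 + 1e-9

    def test_isotropic_data_spreads_variance(self):
        X = np.random.default_rng(123).normal(size=(100, 4))
        red = fit_reducer(_table(X, [0, 1] * 50), variance_target=0.95)
        assert red.n_components <= 4
        full = fit_reducer(_table(X, [0, 1] * 50), variance_target=1.0)
        assert np.ptp(full.explained_variance_ratio) < 0.12

    def test_training_mean_maps_to_origin(self):
        X = RNG.normal(5.0, 2.0, size=(30, 6))
        red = fit_reducer(_table(X, [0, 1] * 15), variance_target=0.9)
        z = transform(red, X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(z, 0.0, atol=1e-9)

    def test_component_cap_is_rows_minus_one(self):
        X = RNG.normal(size=(5, 50))
        red = fit_reducer(_table(X, [0, 1, 0, 1, 0]), variance_target=1.0)
        assert red.n_components <= 4

    def test_zero_variance_columns_dropped(self):
        X = RNG.normal(size=(20, 5))
        X[:, 2] = 3.14
        red = fit_reducer(_table(X, [0, 1] * 10))
        assert list(red.dropped_columns) == [2]
        transform(red, X)  # still accepts the original width

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError, match="3 rows"):
            fit_reducer(_table(RNG.normal(size=(2, 4)), [0, 1]))


class TestTransform:
    def test_full_rank_projection_preserves_distances(self):
        X = RNG.normal(size=(25, 8))
        red = fit_reducer(_table(X, [0, 1] * 12 + [0]), variance_target=1.0)
        Z = transform(red, X)
        kept = red.kept_columns
        Xs = (X[:, kept] - red.mean[kept]) / red.std[kept]
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(Z), pdist(Xs), rtol=1e-8)

    def test_reconstruction_recovers_standardized_data(self):
        X = RNG.normal(size=(30, 6))
        red = fit_reducer(_table(X, [0, 1] * 15), variance_target=1.0)
        Z = transform(red, X)
        back = Z @ red.components
        kept = red.kept_columns
        Xs = (X[:, kept] - red.mean[kept]) / red.std[kept]
        np.testing.assert_allclose(back, Xs, atol=1e-8)

    def test_dimension_mismatch_raises(self):
        X = RNG.normal(size=(10, 4))
        red = fit_reducer(_table(X, [0, 1] * 5))
        with pytest.raises(ValueError, match="mismatch"):
            transform(red, RNG.normal(size=(3, 5)))


class TestClassifiers:
    def _separable(self, n=40, gap=4.0):
        X = np.vstack([
            RNG.normal(size=(n // 2, 2)) + [gap, 0],
            RNG.normal(size=(n // 2, 2)) - [gap, 0],
        ])
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        return X, y

    @pytest.mark.parametrize("backend", classify.BACKENDS)
    def test_separable_training_data_fit_perfectly(self, backend):
        X, y = self._separable()
        model = fit_classifier(X, y, backend=backend, seed=0)
        scores, hard = predict_scores(model, X)
        assert (hard == y).mean() == 1.0

    def test_heldout_points_on_correct_side(self):
        X, y = self._separable()
        model = fit_classifier(X, y, backend="svm", seed=0)
        fresh = np.array([[4.5, 0.3], [-4.5, -0.3]])
        scores, hard = predict_scores(model, fresh)
        assert hard.tolist() == [1, 0]
        assert scores[0] > scores[1]

    def test_deterministic_given_seed(self):
        X = RNG.normal(size=(60, 5))
        y = (X[:, 0] + 0.5 * RNG.normal(size=60) > 0).astype(int)
        s1, _ = predict_scores(fit_classifier(X, y, "rf", seed=4), X)
        s2, _ = predict_scores(fit_classifier(X, y, "rf", seed=4), X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_classifier(RNG.normal(size=(10, 2)), np.zeros(10, int), "svm", 0)

    def test_empty_table_scores_empty(self):
        X, y = self._separable()
        model = fit_classifier(X, y, "svm", 0)
        scores, hard = predict_scores(model, np.empty((0, 2)))
        assert scores.size == 0 and hard.size == 0

    def test_shuffled_labels_give_chance_auc(self):
        # permutation null: features carry no class signal
        from m3.evaluate import compute_metrics, stratified_folds

        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 10))
        y = rng.permutation([0, 1] * 100)
        folds = stratified_folds(y, 5, seed=1)
        aucs = []
        for f in range(5):
            tr, te = folds != f, folds == f
            red = fit_reducer(_table(X[tr], y[tr]), 0.95)
            model = fit_classifier(transform(red, X[tr]), y[tr], "svm", 0)
            s, h = predict_scores(model, transform(red, X[te]))
            aucs.append(compute_metrics(s, h, y[te]).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.12


class TestFusion:
    def test_duplicated_modality_adds_no_information(self):
        X, y = TestClassifiers()._separable(n=30, gap=1.0)
        X = X + RNG.normal(scale=0.5, size=X.shape)
        t = FeatureTable(X=X, y=y, case_ids=[str(i) for i in range(30)], modality="a")
        t2 = FeatureTable(X=X.copy(), y=y, case_ids=t.case_ids, modality="b")
        fused = classify.fuse_modalities([t, t2])
        red1 = fit_reducer(t, 0.95)
        redf = fit_reducer(fused, 0.95)
        s1, _ = predict_scores(
            fit_classifier(transform(red1, t), t.y, "svm", 0), transform(red1, t)
        )
        sf, _ = predict_scores(
            fit_classifier(transform(redf, fused), fused.y, "svm", 0),
            transform(redf, fused),
        )
        from m3.evaluate import compute_metrics

        a1 = compute_metrics(s1, (s1 > 0).astype(int), y).auc
        af = compute_metrics(sf, (sf > 0).astype(int), y).auc
        assert af == pytest.approx(a1, abs=1e-6)

    def test_fused_width_is_sum_of_widths(self):
        tables = [
            FeatureTable(X=RNG.normal(size=(6, 7168)), y=[0, 1] * 3,
                         case_ids=list("abcdef"), modality=m)
            for m in ("t1ce", "t2", "flair")
        ]
        fused = classify.fuse_modalities(tables)
        assert fused.X.shape == (6, 21504)

    def test_score_average_of_identical_scores(self):
        s = RNG.normal(size=12)
        np.testing.assert_allclose(classify.average_scores([s, s.copy()]), s)

    def test_case_mismatch_raises(self):
        t1 = FeatureTable(X=RNG.normal(size=(4, 3)), y=[0, 1, 0, 1],
                          case_ids=list("abcd"))
        t2 = FeatureTable(X=RNG.normal(size=(4, 3)), y=[0, 1, 0, 1],
                          case_ids=list("abce"))
        with pytest.raises(ValueError, match="ordering"):
            classify.fuse_modalities([t1, t2])


class TestNoLeakage:
    def test_heldout_labels_never_touch_fitting(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        y = (X[:, 0] > 0).astype(int)
        tr = np.arange(30)
        te = np.arange(30, 40)
        out = []
        for corrupt in (False, True):
            y2 = y.copy()
            if corrupt:
                y2[te] = 1 - y2[te]
            red = fit_reducer(_table(X[tr], y2[tr]), 0.95)
            model = fit_classifier(transform(red, X[tr]), y2[tr], "svm", 0)
            s, _ = predict_scores(model, transform(red, X[te]))
            out.append(s)
        np.testing.assert_array_equal(out[0], out[1])
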