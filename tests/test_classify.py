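"""PCA projection, linear SVM, LOOCV and the GR/SS/SC metrics."""

import numpy as np
import pytest

from rehomvpa.classify import (
    CONTROL,
    PATIENT,
    ConfusionCounts,
    build_feature_matrix,
    fit_pca,
    loocv,
    metrics,
    train_svm,
)
from rehomvpa.errors import ConfigurationError, DegenerateInputError
from rehomvpa.evaluation import pca_svm_equivalence_max_diff
from rehomvpa.reho import ReHoMap


def _fake_map(values3d, mask):
    kcc = np.where(mask, values3d, np.nan)
    mean = np.nanmean(kcc[mask])
    return ReHoMap(kcc=kcc, computable_mask=mask, normalized=kcc / mean)


class TestBuildFeatureMatrix:
    def test_shape_and_order(self, rng):
        mask = np.ones((5, 5, 5), dtype=bool)
        maps = [_fake_map(np.abs(rng.normal(size=(5, 5, 5))) + 0.1, mask)
                for _ in range(6)]
        labels = [PATIENT] * 3 + [CONTROL] * 3
        fm = build_feature_matrix(maps, labels)
        assert fm.X.shape == (6, 125)
        # reordering subjects permutes rows identically
        perm = [3, 0, 5, 1, 4, 2]
        fm2 = build_feature_matrix([maps[i] for i in perm],
                                   [labels[i] for i in perm])
        np.testing.assert_allclose(fm2.X, fm.X[perm])

    def test_disjoint_masks_error(self, rng):
        m1 = np.zeros((4, 4, 4), dtype=bool)
        m2 = np.zeros((4, 4, 4), dtype=bool)
        m1[:2], m2[2:] = True, True
        vals = np.abs(rng.normal(size=(4, 4, 4))) + 0.1
        maps = [_fake_map(vals, m1), _fake_map(vals, m2)] * 2
        with pytest.raises(ConfigurationError):
            build_feature_matrix(maps, [PATIENT, CONTROL, PATIENT, CONTROL])

    def test_intersection_of_masks_used(self, rng):
        full = np.ones((4, 4, 4), dtype=bool)
        partial = full.copy()
        partial[0, 0, 0] = False
        vals = np.abs(rng.normal(size=(4, 4, 4))) + 0.1
        maps = [_fake_map(vals, full), _fake_map(vals, partial)] * 2
        fm = build_feature_matrix(maps, [PATIENT, CONTROL, PATIENT, CONTROL])
        assert fm.X.shape[1] == 63
        # voxel_index round-trips to 3D coordinates
        scattered = fm.to_map(fm.X[0])
        sel = tuple(fm.voxel_index.T)
        np.testing.assert_allclose(scattered[sel], fm.X[0])


class TestPCA:
    def test_training_rows_reconstruct_exactly(self, rng):
        X = rng.normal(size=(8, 50))
        pca = fit_pca(X)
        recon = pca.mean + pca.project(X) @ pca.U.T
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_mean_projects_to_zero(self, rng):
        pca = fit_pca(rng.normal(size=(6, 30)))
        np.testing.assert_allclose(pca.project(pca.mean), 0.0, atol=1e-10)

    def test_orthonormal_columns_and_dimension(self, rng):
        X = rng.normal(size=(9, 40))
        pca = fit_pca(X)
        assert pca.n_components == 8
        np.testing.assert_allclose(pca.U.T @ pca.U, np.eye(8), atol=1e-8)

    def test_pairwise_distances_preserved(self, rng):
        X = rng.normal(size=(7, 60))
        Y = fit_pca(X).project(X)
        for i in range(7):
            for j in range(i + 1, 7):
                d_full = np.linalg.norm(X[i] - X[j])
                d_red = np.linalg.norm(Y[i] - Y[j])
                assert d_red == pytest.approx(d_full, rel=1e-6)

    def test_single_row_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            fit_pca(rng.normal(size=(1, 10)))


class TestSVM:
    def test_symmetric_pair_passes_through_origin(self):
        Y = np.array([[1.0, 0.5], [-1.0, -0.5]])
        svm = train_svm(Y, [PATIENT, CONTROL])
        assert svm.b == pytest.approx(0.0, abs=1e-6)

    def test_four_point_maximum_margin_geometry(self):
        """Classes at x = +-1 (margin 2): separator is x = 0, w ~ (1, 0)."""
        Y = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        labels = [PATIENT, PATIENT, CONTROL, CONTROL]
        svm = train_svm(Y, labels, C=1.0)
        direction = svm.w / np.linalg.norm(svm.w)
        np.testing.assert_allclose(direction, [1.0, 0.0], atol=1e-4)
        assert svm.b == pytest.approx(0.0, abs=1e-4)

    def test_duplicating_points_leaves_decision_unchanged(self, rng):
        # separable with no active slack, so the solution set is unchanged
        Y = rng.normal(size=(10, 3))
        Y[:5] += 10.0
        labels = np.array([PATIENT] * 5 + [CONTROL] * 5)
        a = train_svm(Y, labels)
        b = train_svm(np.vstack([Y, Y]), np.concatenate([labels, labels]))
        probe = rng.normal(size=(20, 3))
        np.testing.assert_allclose(a.decision(probe), b.decision(probe),
                                   atol=1e-6)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            train_svm(rng.normal(size=(4, 2)), [PATIENT] * 4)

    def test_dual_coefficient_invariants(self, rng):
        Y = rng.normal(size=(12, 4))
        Y[:6] += 0.5
        labels = np.array([PATIENT] * 6 + [CONTROL] * 6)
        svm = train_svm(Y, labels, C=1.0)
        assert np.all(svm.alpha >= -1e-9) and np.all(svm.alpha <= 1.0 + 1e-9)
        assert np.dot(svm.alpha, labels) == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(
            svm.w, (svm.alpha * labels) @ Y, atol=1e-6
        )


class TestLOOCV:
    def test_each_subject_held_out_once(self, toy_features):
        counts, preds, models = loocv(toy_features)
        n = toy_features.X.shape[0]
        assert len(preds) == n and len(models) == n
        assert counts.n == n
        assert counts.tp + counts.fn == (toy_features.labels == PATIENT).sum()
        assert counts.tn + counts.fp == (toy_features.labels == CONTROL).sum()

    def test_fold_pca_dimension_is_n_minus_two(self, toy_features):
        _, _, models = loocv(toy_features)
        n = toy_features.X.shape[0]
        assert all(pca.n_components == n - 2 for pca, _ in models)

    def test_purity_held_out_subject_cannot_change_its_fold(self, toy_features):
        """Perturbing the held-out row leaves that fold's model untouched."""
        fm = toy_features
        _, _, models = loocv(fm)
        X2 = fm.X.copy()
        X2[0] += 100.0
        fm2 = type(fm)(X=X2, labels=fm.labels, voxel_index=fm.voxel_index,
                       mask=fm.mask)
        _, _, models2 = loocv(fm2)
        pca_a, svm_a = models[0]
        pca_b, svm_b = models2[0]
        np.testing.assert_allclose(pca_a.mean, pca_b.mean, atol=1e-12)
        np.testing.assert_allclose(svm_a.w, svm_b.w, atol=1e-10)
        assert svm_a.b == pytest.approx(svm_b.b, abs=1e-10)

    def test_separated_classes_classify_perfectly(self, toy_features):
        counts, _, _ = loocv(toy_features)
        assert metrics(counts)["GR"] == 100.0

    def test_null_features_near_chance(self, rng):
        """Pure-noise features: mean LOOCV accuracy close to 50%."""
        from rehomvpa.classify import FeatureMatrix

        grs = []
        for _ in range(10):
            X = rng.normal(size=(12, 80))
            labels = np.array([PATIENT] * 6 + [CONTROL] * 6)
            mask = np.zeros((5, 4, 4), dtype=bool)
            mask.ravel()[:80] = True
            fm = FeatureMatrix(X=X, labels=labels,
                               voxel_index=np.argwhere(mask), mask=mask)
            counts, _, _ = loocv(fm)
            grs.append(metrics(counts)["GR"])
        assert 25.0 < np.mean(grs) < 75.0


class TestMetrics:
    def test_reported_per_class_accuracies(self):
        m = metrics(ConfusionCounts(tp=25, fn=5, tn=27, fp=3))
        assert m["GR"] == pytest.approx(86.67, abs=0.005)
        assert m["SS"] == pytest.approx(83.33, abs=0.005)
        assert m["SC"] == pytest.approx(90.00, abs=0.005)

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=30, tn=30, fp=0, fn=0))
        assert m == {"GR": 100.0, "SS": 100.0, "SC": 100.0}

    def test_all_wrong(self):
        m = metrics(ConfusionCounts(tp=0, tn=0, fp=5, fn=5))
        assert m["GR"] == 0.0

    def test_weighted_identity(self, rng):
        for _ in range(20):
            tp, fn, tn, fp = rng.integers(1, 30, size=4)
            m = metrics(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
            n_pat, n_con = tp + fn, tn + fp
            recombined = (m["SS"] * n_pat + m["SC"] * n_con) / (n_pat + n_con)
            assert m["GR"] == pytest.approx(recombined, abs=1e-9)

    def test_empty_counts_flagged(self):
        with pytest.raises(DegenerateInputError):
            metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))


def test_reduced_space_svm_equals_voxel_space_svm():
    """All N-1 components preserve the centered Gram matrix exactly."""
    assert pca_svm_equivalence_max_diff(n=12, d=200) < 1e-6
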