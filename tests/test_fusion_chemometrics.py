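import numpy as np
import pytest
from scipy import stats

from barleyauth import fusion_chemometrics as fc
from barleyauth import isotope_stats as iso
from barleyauth.spectra_prep import BinnedSpectrum


def _table(matrix, labels, names=None, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    names = names or [f"v{j}" for j in range(matrix.shape[1])]
    ids = ids or [f"s{i}" for i in range(matrix.shape[0])]
    return fc.FeatureTable(matrix, names, np.asarray(labels), ids)


class TestFuse:
    def test_quench_table_shape_and_header(self, quench_table):
        assert quench_table.matrix.shape == (39, 303)
        assert quench_table.variable_names[-3:] == ["d13C", "d15N", "d18O"]
        centers = [float(n[4:]) for n in quench_table.variable_names[:300]]
        assert centers == sorted(centers)

    def test_single_sample_row_carries_its_isotopes(self):
        b = BinnedSpectrum(np.linspace(4000, 11000, 300), np.ones(300))
        rec = iso.IsotopeRecord("s1", "Quench", 2017, -27.0, 3.1, 29.5)
        # a lone sample cannot be classified but can be fused
        t = fc.FeatureTable(
            np.zeros((1, 3)), ["a", "b", "c"], np.array([2017]), ["x"]
        )  # sanity that 1-row tables are legal containers
        del t
        table = fc.fuse({"s1": b}, [rec])
        assert table.matrix.shape == (1, 303)
        assert tuple(table.matrix[0, -3:]) == (-27.0, 3.1, 29.5)

    def test_modality_mismatch_lists_offenders(self):
        b = BinnedSpectrum(np.linspace(4000, 11000, 300), np.ones(300))
        rec = iso.IsotopeRecord("s1", "Quench", 2017, -27.0, 3.1, 29.5)
        with pytest.raises(ValueError, match="s1"):
            fc.fuse({"other": b}, [rec])


class TestKruskalWallis:
    def test_constant_variable_scores_zero(self):
        t = _table([[1, 5], [1, 6], [1, 7], [1, 8]], [2017, 2017, 2018, 2018])
        scores = {s.variable_name: s for s in fc.kw_filter_scores(t)}
        assert scores["v0"].H == 0.0
        assert scores["v0"].rank == 2

    def test_maximal_separation_of_four_values(self):
        t = _table([[1], [2], [3], [4]], [2017, 2017, 2018, 2018])
        (score,) = fc.kw_filter_scores(t)
        # 12/(4*5) * [2*(1.5-2.5)^2 + 2*(3.5-2.5)^2] = 2.4
        assert score.H == pytest.approx(2.4)
        assert score.H == pytest.approx(
            stats.kruskal([1, 2], [3, 4]).statistic
        )

    def test_tie_correction_matches_scipy(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 4, 12).astype(float)  # heavy ties
        labels = np.array([2017] * 6 + [2018] * 6)
        t = _table(col[:, None], labels)
        (score,) = fc.kw_filter_scores(t)
        assert score.H == pytest.approx(
            stats.kruskal(col[:6], col[6:]).statistic
        )

    def test_ranking_matches_mww_distance_from_center(self):
        # for two tie-free classes, H orders variables exactly as
        # |U - n_a n_b / 2| does
        rng = np.random.default_rng(0)
        for _ in range(30):
            X = rng.permuted(
                np.tile(np.arange(6, dtype=float), (4, 1)).T
                + rng.normal(0, 0.01, (6, 4)),
                axis=0,
            )
            labels = np.array([2017] * 3 + [2018] * 3)
            t = _table(X, labels)
            hs = np.array([s.H for s in fc.kw_filter_scores(t)])
            us = np.array(
                [
                    abs(iso.mww_test(X[:3, j], X[3:, j]).U - 9 / 2)
                    for j in range(4)
                ]
            )
            for i in range(4):
                for j in range(4):
                    if us[i] < us[j]:
                        assert hs[i] < hs[j] + 1e-12

    def test_requires_two_classes_with_two_samples(self):
        t = _table([[1], [2], [3]], [2017, 2017, 2018])
        with pytest.raises(ValueError, match="fewer than 2"):
            fc.kw_filter_scores(t)


class TestSelection:
    def test_top_k_full_is_identity(self, quench_table):
        scores = fc.kw_filter_scores(quench_table)
        out = fc.select_top_k(scores, quench_table, k=303)
        assert out.variable_names == quench_table.variable_names

    def test_top_50_retains_exactly_50(self, quench_table):
        scores = fc.kw_filter_scores(quench_table)
        out = fc.select_top_k(scores, quench_table, k=50)
        assert out.n_variables == 50
        # survivors keep original column order
        pos = {v: i for i, v in enumerate(quench_table.variable_names)}
        assert [pos[v] for v in out.variable_names] == sorted(
            pos[v] for v in out.variable_names
        )

    def test_constant_variable_never_selected(self):
        rng = np.random.default_rng(1)
        X = np.column_stack(
            [np.ones(8), rng.normal(0, 1, 8), np.r_[np.zeros(4), np.ones(4) * 5]]
        )
        t = _table(X, [2017] * 4 + [2018] * 4)
        out = fc.select_top_k(fc.kw_filter_scores(t), t, k=2)
        assert "v0" not in out.variable_names

    def test_k_too_large_rejected(self, quench_table):
        scores = fc.kw_filter_scores(quench_table)
        with pytest.raises(ValueError, match="exceeds"):
            fc.select_top_k(scores, quench_table, k=304)


class TestAutoscale:
    def test_simple_column(self):
        t = _table([[1.0], [2.0], [3.0]], [2017, 2017, 2018])
        scaled, means, sds = fc.autoscale(t)
        assert np.allclose(scaled.matrix[:, 0], [-1, 0, 1])
        assert means[0] == 2.0 and sds[0] == 1.0

    def test_column_moments(self, quench_table):
        scaled, _, _ = fc.autoscale(quench_table)
        assert np.max(np.abs(scaled.matrix.mean(axis=0))) < 1e-12
        assert np.max(np.abs(scaled.matrix.std(axis=0, ddof=1) - 1)) < 1e-12

    def test_heldout_rows_use_training_parameters(self):
        train = _table([[0.0], [2.0]], [2017, 2018])
        _, means, sds = fc.autoscale(train)
        held = _table([[4.0]], [2018])
        out = fc.apply_autoscale(held, means, sds)
        assert out.matrix[0, 0] == pytest.approx((4.0 - 1.0) / np.sqrt(2.0))

    def test_zero_variance_column_named_in_error(self):
        t = _table([[1.0, 1.0], [1.0, 2.0]], [2017, 2018], names=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            fc.autoscale(t)


class TestPCA:
    def test_two_samples_load_one_component(self):
        t = _table([[1.0, -2.0, 3.0], [-1.0, 2.0, -3.0]], [2017, 2018])
        model, scores = fc.pca_fit(t, n_components=1)
        assert model.explained_variance_pct[0] == pytest.approx(100.0)

    def test_scores_uncorrelated_and_variance_conserved(self, quench_table):
        scaled, _, _ = fc.autoscale(quench_table)
        rank = min(scaled.matrix.shape[0] - 1, scaled.matrix.shape[1])
        model, scores = fc.pca_fit(scaled, n_components=rank)
        r = np.corrcoef(scores[:, 0], scores[:, 1])[0, 1]
        assert abs(r) < 1e-10
        assert np.diff(model.explained_variance_pct).max() <= 1e-12
        assert model.explained_variance_pct.sum() == pytest.approx(100.0)

    def test_reconstruction_and_orthogonal_residual(self, quench_table):
        scaled, _, _ = fc.autoscale(quench_table)
        model, scores = fc.pca_fit(scaled, n_components=2)
        recon = scores @ model.loadings.T
        residual = scaled.matrix - recon
        assert np.max(np.abs(residual @ model.loadings)) < 1e-9
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(2), atol=1e-12)

    def test_matches_sklearn_decomposition(self, quench_table):
        sklearn = pytest.importorskip("sklearn.decomposition")
        scaled, _, _ = fc.autoscale(quench_table)
        model, scores = fc.pca_fit(scaled, n_components=2)
        ref = sklearn.PCA(n_components=2, svd_solver="full")
        ref_scores = ref.fit_transform(scaled.matrix)
        # centered data: same subspace up to sign
        for k in range(2):
            assert abs(
                abs(np.corrcoef(scores[:, k], ref_scores[:, k])[0, 1]) - 1
            ) < 1e-8

    def test_component_count_bound(self):
        t = _table([[0.0, 1.0], [1.0, 0.0]], [2017, 2018])
        with pytest.raises(ValueError, match="exceeds"):
            fc.pca_fit(t, n_components=2)


class TestCentroidClassifier:
    def test_unit_circle_closed_form(self):
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        clf = fc.fit_centroid_classifier(pts, np.zeros(8, dtype=int))
        assert np.allclose(clf.centroids[0], 0, atol=1e-12)
        assert clf.radial_scales[0] == pytest.approx(np.sqrt(0.5))
        assert clf.radii[0] == pytest.approx(np.sqrt(5.991464547107979 / 2.0))

    def test_invariant_under_duplication(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1, (10, 2))
        labels = np.array([0] * 5 + [1] * 5)
        a = fc.fit_centroid_classifier(pts, labels)
        b = fc.fit_centroid_classifier(np.vstack([pts, pts]), np.r_[labels, labels])
        assert np.allclose(a.centroids, b.centroids)
        assert np.allclose(a.radii, b.radii)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 1, (12, 2))
        labels = np.array([0] * 6 + [1] * 6)
        v = np.array([3.5, -1.25])
        a = fc.fit_centroid_classifier(pts, labels)
        b = fc.fit_centroid_classifier(pts + v, labels)
        assert np.allclose(b.centroids, a.centroids + v)
        assert np.allclose(b.radii, a.radii)

    def test_classify_centroid_and_outlier(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]], float)
        labels = np.array([2017] * 3 + [2018] * 3)
        clf = fc.fit_centroid_classifier(pts, labels)
        pred = fc.classify(clf, np.array([clf.centroids[0], [100.0, 100.0]]))
        assert pred[0] == 2017
        assert pred[1] == fc.UNASSIGNED
        assert fc.accuracy(pred, [2017, 2018]) == 50.0

    def test_small_class_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            fc.fit_centroid_classifier(pts, np.array([0, 0, 1]))

    def test_degenerate_class_dispersion_rejected(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [6.0, 6.0]])
        with pytest.raises(ValueError, match="zero score dispersion"):
            fc.fit_centroid_classifier(pts, np.array([0, 0, 1, 1]))


class TestMonteCarloCV:
    def _separable(self, n=20):
        # two rings far apart: bounded within-class scatter, so every
        # point falls inside its class's 95% radius by construction
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        ring = 0.1 * np.column_stack([np.cos(theta), np.sin(theta)])
        X = np.vstack([ring, ring + 5.0])
        return _table(X, [2017] * n + [2018] * n)

    def test_separable_data_scores_100(self):
        cv = fc.monte_carlo_cv(self._separable(), n_iter=20, k=2, seed=0)
        assert cv.mean_accuracy == 100.0

    def test_seed_reproducibility(self):
        t = self._separable()
        a = fc.monte_carlo_cv(t, n_iter=5, k=2, seed=42)
        b = fc.monte_carlo_cv(t, n_iter=5, k=2, seed=42)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_accuracies_bounded_and_counted(self):
        cv = fc.monte_carlo_cv(self._separable(), n_iter=7, k=2, seed=1)
        assert cv.accuracies.shape == (7,)
        assert np.all((cv.accuracies >= 0) & (cv.accuracies <= 100))

    def test_training_fit_ignores_test_rows(self, quench_table):
        # leakage guard: perturbing held-out rows must not change anything
        # fitted from the training rows
        idx = np.arange(quench_table.n_samples)
        train_idx = np.r_[idx[:15], idx[20:35]]
        corrupted = fc.FeatureTable(
            quench_table.matrix.copy(),
            list(quench_table.variable_names),
            quench_table.labels,
            list(quench_table.sample_ids),
            quench_table.cultivar,
        )
        test_mask = np.ones(quench_table.n_samples, dtype=bool)
        test_mask[train_idx] = False
        corrupted.matrix[test_mask] = 1e6  # wreck the held-out rows only
        direct = fc.fit_pipeline(quench_table.subset_rows(train_idx), k=50)
        other = fc.fit_pipeline(corrupted.subset_rows(train_idx), k=50)
        assert direct.selected == other.selected
        assert np.array_equal(direct.pca.loadings, other.pca.loadings)
        assert np.array_equal(direct.pca.column_means, other.pca.column_means)
        assert np.array_equal(
            direct.classifier.centroids, other.classifier.centroids
        )
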