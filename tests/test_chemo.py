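"""PCA/OPLS-DA against independent oracles, VIP identity, permutation test."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from herbqc import chemo, synth
from herbqc.chemo import (
    ChemometricsError,
    LatentModel,
    encode_labels,
    oplsda,
    pca,
    permutation_test,
    preprocess,
    s_plot,
    select_markers,
    vip,
)
from herbqc.peaks import PeakTable


class TestPreprocess:
    def test_autoscale_gives_zero_mean_unit_variance(self, default_table):
        table, _ = default_table
        X, _ = preprocess(table, "autoscale")
        assert np.allclose(X.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(X.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_center_preserves_column_variances(self, default_table):
        table, _ = default_table
        X, _ = preprocess(table, "center")
        assert np.allclose(X.std(axis=0, ddof=1), table.areas.std(axis=0, ddof=1))

    def test_stored_parameters_reproduce_the_transform(self, default_table):
        table, _ = default_table
        X, prep = preprocess(table, "pareto")
        assert np.allclose(prep.apply(table.areas), X)
        assert np.allclose(prep.invert(X), table.areas)

    def test_zero_variance_column_rejected_by_name(self):
        table = PeakTable(
            batch_ids=["a", "b", "c"], regions=["HN", "HN", "HB"],
            peak_ids=["P1", "P2"],
            areas=np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]),
        )
        with pytest.raises(ChemometricsError, match="P2"):
            preprocess(table, "autoscale")
        X, _ = preprocess(table, "center")  # centering is still fine
        assert X.shape == (3, 2)


class TestPCA:
    def test_rank_one_matrix_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.normal(size=8), rng.normal(size=5))
        model = pca(X, n_components=1)
        assert model.explained[0] == pytest.approx(1.0)

    def test_orthonormal_loadings_and_orthogonal_scores(self, default_table):
        table, _ = default_table
        X, _ = preprocess(table, "autoscale")
        model = pca(X, n_components=4)
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(4), atol=1e-10)
        gram = model.scores.T @ model.scores
        assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-8)

    def test_matches_covariance_eigendecomposition_oracle(self):
        """Explained variances equal covariance eigenvalues (independent route)."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(4, 13)
            p = rng.integers(2, 13)
            X = rng.normal(size=(n, p))
            X = X - X.mean(axis=0)
            k = int(min(n - 1, p))
            model = pca(X, n_components=k)
            eigvals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
            expected = eigvals[:k] / eigvals.sum()
            np.testing.assert_allclose(model.explained, expected[: len(model.explained)],
                                       rtol=1e-8, atol=1e-12)

    def test_excessive_components_rejected(self):
        X = np.random.default_rng(1).normal(size=(5, 3))
        with pytest.raises(ChemometricsError):
            pca(X - X.mean(axis=0), n_components=5)

    def test_hotelling_ellipse_reported(self, default_table):
        table, _ = default_table
        X, _ = preprocess(table, "autoscale")
        model = pca(X, n_components=2)
        assert model.hotelling is not None and model.hotelling["t2_crit"] > 0


class TestOPLSDA:
    def test_zero_orthogonal_components_equals_pls1_oracle(self, default_table):
        """With no orthogonal filtering the model IS single-component PLS1."""
        table, _ = default_table
        X, _ = preprocess(table, "autoscale")
        y, _ = encode_labels(table.regions)
        model = oplsda(X, y, n_orthogonal=0)
        sk = PLSRegression(n_components=1, scale=False).fit(X, y)
        ours = model.predict(X) + model.extras["y_mean"]
        np.testing.assert_allclose(ours, sk.predict(X).ravel(), atol=1e-8)

    def test_predictive_scores_orthogonal_to_orthogonal_scores(self, fitted_model):
        model, _, _ = fitted_model
        t = model.scores[:, 0]
        for a in range(model.n_orthogonal):
            assert abs(t @ model.orthogonal_scores[:, a]) < 1e-8

    def test_fit_quality_on_planted_regional_effects(self):
        """Strong planted contrasts give a well-fitting, predictive model."""
        for seed in range(5):
            table, _ = synth.simulate_batch_set(seed=seed)
            X, _ = preprocess(table, "autoscale")
            y, _ = encode_labels(table.regions)
            model = oplsda(X, y, n_orthogonal=1)
            assert model.R2Y > 0.8 and model.Q2 > 0.4

    def test_single_class_rejected(self, default_table):
        table, _ = default_table
        X, _ = preprocess(table, "autoscale")
        with pytest.raises(ChemometricsError):
            oplsda(X, np.ones(X.shape[0]))

    def test_r2x_components_within_unit_interval(self, fitted_model):
        model, _, _ = fitted_model
        assert (model.explained >= 0).all()
        assert 0 < model.R2X_cum <= 1


class TestVIP:
    def test_mean_square_is_exactly_one(self, fitted_model):
        model, _, _ = fitted_model
        assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-9)

    def test_equal_weights_give_unit_vip(self):
        p = 6
        model = LatentModel(
            kind="oplsda", scores=np.zeros((4, 1)), loadings=np.zeros((p, 1)),
            explained=np.array([1.0]), R2X_cum=1.0,
            weights=np.full(p, 1 / np.sqrt(p)),
        )
        assert np.allclose(vip(model), 1.0)

    def test_informative_variable_dominates(self):
        rng = np.random.default_rng(7)
        y = np.array([1.0] * 6 + [-1.0] * 6)
        X = rng.normal(size=(12, 8))
        X[:, 3] = y + rng.normal(scale=0.2, size=12)
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        model = oplsda(X, y, n_orthogonal=0)
        assert int(np.argmax(model.vip)) == 3
        assert model.vip[3] > 1


class TestSPlot:
    def test_variable_equal_to_score_has_unit_correlation(self):
        rng = np.random.default_rng(11)
        y = np.array([1.0] * 5 + [-1.0] * 5)
        X = rng.normal(size=(10, 4))
        X[:, 0] = y * 2.0
        X = X - X.mean(axis=0)
        model = oplsda(X, y, n_orthogonal=0)
        sp = s_plot(model, X)
        # the predictive score is dominated by column 0
        assert sp[0, 1] == pytest.approx(1.0, abs=0.02)

    def test_covariance_and_correlation_share_signs(self, fitted_model):
        model, X, _ = fitted_model
        sp = model.splot
        nz = np.abs(sp[:, 0]) > 1e-12
        assert np.all(np.sign(sp[nz, 0]) == np.sign(sp[nz, 1]))

    def test_zero_variance_variable_reported_missing(self, fitted_model):
        model, X, _ = fitted_model
        X2 = X.copy()
        X2[:, 2] = 1.5  # constant
        sp = s_plot(model, X2)
        assert np.isnan(sp[2, 1]) and not np.isnan(sp[2, 0])

    def test_planted_markers_occupy_extreme_covariances(self, default_table,
                                                        fitted_model):
        table, _ = default_table
        model, _, _ = fitted_model
        order = np.argsort(-np.abs(model.splot[:, 0]))
        top = {table.peak_ids[j] for j in order[:7]}
        assert top == set(synth.MARKER_PEAKS)


class TestPermutation:
    def test_unpermuted_point_anchors_the_regression(self, default_table):
        table, _ = default_table
        X, _ = preprocess(table, "autoscale")
        y, _ = encode_labels(table.regions)
        _, _, frame = permutation_test(X, y, n_perm=20, seed=0)
        assert frame.iloc[0]["correlation"] == 1.0
        assert not frame.iloc[0]["permuted"]
        assert len(frame) == 21

    def test_strong_signal_beats_every_permutation(self, default_table):
        table, _ = default_table
        X, _ = preprocess(table, "autoscale")
        y, _ = encode_labels(table.regions)
        _, _, frame = permutation_test(X, y, n_perm=50, seed=1)
        original_q2 = frame.loc[~frame["permuted"], "Q2"].iloc[0]
        assert (frame.loc[frame["permuted"], "Q2"] < original_q2).all()

    def test_seed_reproducible(self, default_table):
        table, _ = default_table
        X, _ = preprocess(table, "autoscale")
        y, _ = encode_labels(table.regions)
        a = permutation_test(X, y, n_perm=25, seed=5)
        b = permutation_test(X, y, n_perm=25, seed=5)
        assert a[0] == b[0] and a[1] == b[1]
        assert a[2].equals(b[2])

    def test_noise_only_data_has_flat_regression(self):
        """With no class signal the fitted line is flat: the intercept sits at
        the mean permuted Q2."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(18, 18))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        y = np.array([1.0] * 9 + [-1.0] * 9)
        _, q2_icpt, frame = permutation_test(X, y, n_perm=100, seed=3)
        assert abs(q2_icpt - frame.loc[frame["permuted"], "Q2"].mean()) < 0.1

    def test_too_few_permutations_rejected(self, fitted_model):
        _, X, y = fitted_model
        with pytest.raises(ChemometricsError):
            permutation_test(X, y, n_perm=5)


class TestSelectMarkers:
    def test_identical_groups_select_nothing(self):
        rng = np.random.default_rng(0)
        block = rng.uniform(1, 5, size=(9, 6))
        table = PeakTable(
            batch_ids=[f"b{i}" for i in range(18)],
            regions=["HN"] * 9 + ["HB"] * 9,
            peak_ids=[f"P{j}" for j in range(6)],
            areas=np.vstack([block, block]),  # identical distributions
        )
        model = LatentModel(
            kind="oplsda", scores=np.zeros((18, 1)), loadings=np.zeros((6, 1)),
            explained=np.array([0.1]), R2X_cum=0.1,
            weights=np.full(6, 1 / np.sqrt(6)),
        )
        model.vip = vip(model)
        assert not any(r.selected for r in select_markers(table, model))

    def test_high_vip_alone_is_not_enough(self):
        """Selection is the conjunction VIP > 1 AND p < 0.05."""
        rng = np.random.default_rng(1)
        areas = rng.uniform(4, 5, size=(12, 3))
        table = PeakTable(
            batch_ids=[f"b{i}" for i in range(12)],
            regions=["HN"] * 6 + ["HB"] * 6,
            peak_ids=["A", "B", "C"],
            areas=areas,
        )
        model = LatentModel(
            kind="oplsda", scores=np.zeros((12, 1)), loadings=np.zeros((3, 1)),
            explained=np.array([0.5]), R2X_cum=0.5,
            weights=np.array([0.9, 0.3, 0.3]),
        )
        model.vip = vip(model)
        report = {r.peak_id: r for r in select_markers(table, model)}
        assert report["A"].vip > 1 and report["A"].p_value > 0.05
        assert not report["A"].selected

    def test_planted_markers_recovered(self, default_table, fitted_model):
        table, _ = default_table
        model, _, _ = fitted_model
        selected = {r.peak_id for r in select_markers(table, model) if r.selected}
        assert selected == set(synth.MARKER_PEAKS)

    def test_report_sorted_by_vip(self, default_table, fitted_model):
        table, _ = default_table
        model, _, _ = fitted_model
        vips = [r.vip for r in select_markers(table, model)]
        assert vips == sorted(vips, reverse=True)
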