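"""Feature constructions: supervised edge reduction, PCA coefficients, fALFF."""

import numpy as np
import pytest

from fcage import components as cp
from fcage import connectome as cn
from fcage import features as ft


def standardized(X):
    return (X - X.mean(0)) / X.std(0)


class TestSupervisedReductionClosedForm:
    def test_first_loading_is_normalized_cross_covariance(self, rng):
        """p1 = X'Y / ||X'Y|| maximizes Cov(Xp, Y) under a unit-norm
        constraint (Cauchy-Schwarz); 100 random instances to 1e-10."""
        for _ in range(100):
            n, m = rng.integers(6, 30), rng.integers(2, 15)
            X = rng.normal(size=(n, m))
            Y = rng.normal(size=n)
            red = ft.fit_supervised_reduction(X, Y, l=1)
            Xs = standardized(X)
            Ys = (Y - Y.mean()) / Y.std()
            w = Xs.T @ Ys
            np.testing.assert_allclose(
                red.loadings[:, 0], w / np.linalg.norm(w), atol=1e-10)

    def test_grid_search_confirms_covariance_maximizer_at_m2(self, rng):
        X = rng.normal(size=(25, 2))
        Y = rng.normal(size=25)
        red = ft.fit_supervised_reduction(X, Y, l=1)
        Xs, Ys = standardized(X), (Y - Y.mean()) / Y.std()
        best, best_cov = None, -np.inf
        for theta in np.linspace(0, 2 * np.pi, 20001):
            p = np.array([np.cos(theta), np.sin(theta)])
            c = float((Xs @ p) @ Ys)
            if c > best_cov:
                best, best_cov = p, c
        assert np.abs(red.loadings[:, 0] - best).max() < 1e-3

    def test_orthogonal_response_stops_early(self, rng):
        n = 20
        Y = rng.normal(size=n)
        X = rng.normal(size=(n, 5))
        Yc = Y - Y.mean()
        # remove the response direction from every centered column
        X = X - np.outer(Yc, (Yc @ X) / (Yc @ Yc))
        red = ft.fit_supervised_reduction(X, Y, l=2)
        assert red.early_stop and red.l == 0

    def test_l_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            ft.fit_supervised_reduction(rng.normal(size=(5, 3)), rng.normal(size=5), l=5)


class TestSupervisedReductionStructure:
    @pytest.fixture()
    def fitted(self, rng):
        X = rng.normal(size=(30, 12))
        Y = 2.0 * X[:, 0] - X[:, 3] + rng.normal(size=30)
        return X, Y, ft.fit_supervised_reduction(X, Y, l=4)

    def test_unit_norm_loadings(self, fitted):
        _, _, red = fitted
        np.testing.assert_allclose(
            np.linalg.norm(red.loadings, axis=0), 1.0, atol=1e-10)

    def test_component_orthogonality(self, fitted):
        _, _, red = fitted
        G = red.projections.T @ red.projections
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8 * np.abs(np.diag(G)).max()

    def test_residual_orthogonal_to_components(self, fitted):
        X, Y, red = fitted
        Xs = standardized(X)
        E = Xs.copy()
        for k in range(red.l):
            E = E - np.outer(red.projections[:, k], red.x_coeffs[:, k])
        assert np.abs(red.projections.T @ E).max() < 1e-8

    def test_energy_conservation(self, fitted):
        X, Y, red = fitted
        Xs = standardized(X)
        E = Xs.copy()
        captured = 0.0
        for k in range(red.l):
            uk, ck = red.projections[:, k], red.x_coeffs[:, k]
            captured += np.sum(np.outer(uk, ck) ** 2)
            E = E - np.outer(uk, ck)
        assert np.sum(Xs**2) == pytest.approx(captured + np.sum(E**2), abs=1e-8)

    def test_matches_sklearn_pls_first_component(self, rng):
        """Independent cross-check: the first loading direction coincides
        with PLS regression's first x-weight for a univariate response."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(40, 8))
        Y = X[:, 1] + 0.5 * rng.normal(size=40)
        red = ft.fit_supervised_reduction(X, Y, l=2)
        pls = PLSRegression(n_components=2, scale=True).fit(X, Y)
        w = pls.x_weights_[:, 0]
        sign = np.sign(w @ red.loadings[:, 0])
        np.testing.assert_allclose(red.loadings[:, 0], sign * w, atol=1e-8)

    def test_brute_force_deflation_oracle(self, rng):
        """n=8, m=3, l=2: loadings/components match direct covariance
        maximization (dense optimization on the unit sphere) plus deflation."""
        from scipy.optimize import minimize

        X = rng.normal(size=(8, 3))
        Y = rng.normal(size=8)
        red = ft.fit_supervised_reduction(X, Y, l=2)

        Xs, Ys = standardized(X), (Y - Y.mean()) / Y.std()

        def best_direction(E, f):
            def neg_cov(p):
                p = p / np.linalg.norm(p)
                return -float((E @ p) @ f)
            best = None
            for s in range(12):
                p0 = np.random.default_rng(s).normal(size=3)
                res = minimize(neg_cov, p0, method="Nelder-Mead",
                               options={"xatol": 1e-12, "fatol": 1e-14,
                                        "maxiter": 5000})
                if best is None or res.fun < best.fun:
                    best = res
            return best.x / np.linalg.norm(best.x)

        E, f = Xs.copy(), Ys.copy()
        for k in range(2):
            p = best_direction(E, f)
            if p @ red.loadings[:, k] < 0:
                p = -p
            np.testing.assert_allclose(red.loadings[:, k], p, atol=1e-6)
            u = E @ p
            np.testing.assert_allclose(red.projections[:, k], u, atol=1e-6)
            c = E.T @ u / (u @ u)
            r = (f @ u) / (u @ u)
            E = E - np.outer(u, c)
            f = f - r * u


class TestTransform:
    def test_training_transform_reproduces_projections(self, rng):
        X = rng.normal(size=(25, 10))
        Y = rng.normal(size=25)
        red = ft.fit_supervised_reduction(X, Y, l=3)
        block = ft.transform_supervised(red, X)
        np.testing.assert_allclose(block.matrix, red.projections, atol=1e-10)

    def test_single_subject_stateless(self, rng):
        X = rng.normal(size=(25, 10))
        Y = rng.normal(size=25)
        red = ft.fit_supervised_reduction(X, Y, l=3)
        before = red.loadings.copy()
        row = ft.transform_supervised(red, X[7:8])
        assert row.matrix.shape == (1, 3)
        np.testing.assert_allclose(row.matrix[0], red.projections[7], atol=1e-10)
        np.testing.assert_array_equal(red.loadings, before)

    def test_edge_set_mismatch_rejected(self, rng):
        red = ft.fit_supervised_reduction(
            rng.normal(size=(20, 8)), rng.normal(size=20), l=2)
        with pytest.raises(ValueError):
            ft.transform_supervised(red, rng.normal(size=(3, 9)))

    def test_shared_truth_transfer_keeps_age_signal(self, paired_cohorts):
        """u1 of an externally transformed shared-truth cohort stays
        age-correlated (threshold from the pre-build oracle regime)."""
        internal, external = paired_cohorts
        D_int = cn.build_cohort_matrix(internal)
        D_ext = cn.build_cohort_matrix(external)
        red = ft.fit_supervised_reduction(D_int.values.T, internal.ages, l=5)
        U_ext = ft.transform_supervised(red, D_ext.values.T).matrix
        r = np.corrcoef(U_ext[:, 0], external.ages)[0, 1]
        assert abs(r) > 0.5


class TestNetworkFeatures:
    def test_training_rows_equal_decomposition_coefficients(self, rng):
        D = rng.normal(size=(45, 12))
        dec = cp.fit_components(D)
        block = ft.network_features(dec, D, L=8)
        np.testing.assert_allclose(block.matrix, dec.coefficients[:, :8], atol=1e-8)

    def test_pure_component_projects_to_unit_coefficient(self, rng):
        D = rng.normal(size=(45, 12))
        dec = cp.fit_components(D)
        block = ft.network_features(dec, dec.components[:, [0]], L=5)
        np.testing.assert_allclose(block.matrix[0, 0], 1.0, atol=1e-8)
        np.testing.assert_allclose(block.matrix[0, 1:], 0.0, atol=1e-8)

    def test_full_rank_features_reconstruct_subjects(self, rng):
        D = rng.normal(size=(45, 12))
        dec = cp.fit_components(D)
        block = ft.network_features(dec, D)
        recon = dec.components @ block.matrix.T
        np.testing.assert_allclose(recon, D, atol=1e-8)


class TestTemporalFeatures:
    def test_transpose_and_order(self, rng):
        values = rng.uniform(0.4, 0.8, size=(6, 9))

        class F:
            pass

        f = F()
        f.values = values
        f.node_ids = np.arange(6)
        block = ft.temporal_features(f)
        assert block.matrix.shape == (9, 6)
        np.testing.assert_array_equal(block.matrix, values.T)
        assert block.feature_names == [f"falff_node_{i}" for i in range(6)]


class TestLeakageContract:
    def test_strict_mode_never_sees_held_out_ages(self, small_cohort):
        """Instrumented pipeline records every age vector it is fitted on;
        in strict K-fold none may include a held-out subject's age."""
        from fcage.prediction import ModelSpec, kfold_validate

        D = cn.build_cohort_matrix(small_cohort)
        ages = small_cohort.ages
        seen = []

        class SpyPipeline(ft.EdgeFeaturePipeline):
            def fit(self, cols, ages_train):
                seen.append(np.asarray(ages_train).copy())
                return super().fit(cols, ages_train)

        res = kfold_validate(
            ModelSpec(family="ols"), lambda: SpyPipeline(l=3), D.values,
            small_cohort.metadata, K=4, seed=0, leakage_mode="strict")
        folds = res.table["fold"].to_numpy()
        assert len(seen) == 4
        for f_idx, ages_seen in enumerate(seen):
            held_out = ages[folds == f_idx]
            train = ages[folds != f_idx]
            np.testing.assert_array_equal(np.sort(ages_seen), np.sort(train))
            assert not np.intersect1d(ages_seen, held_out).size
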