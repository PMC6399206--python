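"""Cross-subject PCA and component characterization."""

import numpy as np
import pytest

from fcage import components as cp
from fcage import connectome as cn


def random_D(m=50, n=20, seed=0):
    return np.random.default_rng(seed).normal(size=(m, n))


class TestFitComponents:
    def test_hand_eigendecomposition(self):
        D = np.array([[2.0, 0.0], [0.0, 1.0]])
        dec = cp.fit_components(D)
        np.testing.assert_allclose(dec.explained_variance, [0.8, 0.2], atol=1e-12)
        np.testing.assert_allclose(np.abs(dec.components[:, 0]), [2, 0], atol=1e-12)
        np.testing.assert_allclose(np.abs(dec.components[:, 1]), [0, 1], atol=1e-12)

    def test_full_rank_reconstruction(self):
        D = random_D()
        dec = cp.fit_components(D)
        recon = dec.components @ dec.coefficients.T
        assert np.max(np.abs(D - recon)) < 1e-10 * np.max(np.abs(D))

    def test_matches_svd_oracle_up_to_sign(self):
        D = random_D()
        dec = cp.fit_components(D)
        U, S, Vt = np.linalg.svd(D, full_matrices=False)
        T_oracle = U * S                       # columns = D @ right singular vectors
        for j in range(dec.n_components):
            a, b = dec.components[:, j], T_oracle[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_explained_variance_non_increasing_and_sums_to_one(self):
        dec = cp.fit_components(random_D(seed=5))
        assert np.all(np.diff(dec.explained_variance) <= 1e-12)
        assert dec.explained_variance.sum() == pytest.approx(1.0, abs=1e-10)

    def test_component_orthogonality(self):
        dec = cp.fit_components(random_D(seed=2))
        G = dec.components.T @ dec.components
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_L_exceeding_subjects_rejected(self):
        with pytest.raises(ValueError):
            cp.fit_components(random_D(), L=21)

    def test_subject_relabeling_permutes_coefficient_rows_only(self):
        D = random_D(seed=9)
        perm = np.random.default_rng(1).permutation(D.shape[1])
        a = cp.fit_components(D)
        b = cp.fit_components(D[:, perm])
        np.testing.assert_allclose(b.coefficients, a.coefficients[perm], atol=1e-8)
        np.testing.assert_allclose(b.components, a.components, atol=1e-8)


class TestSubjectExpansion:
    def test_all_components_recover_subject_exactly(self):
        D = random_D(m=15, n=6, seed=3)  # m = 15 -> 6-node matrices
        dec = cp.fit_components(D)
        i = 4
        M = cp.subject_expansion(dec, i, node_count=6)
        np.testing.assert_allclose(cn.vectorize(M), D[:, i], atol=1e-10)
        assert np.all(np.diag(M) == 1.0)

    def test_rank_one_residual_equals_tail_energy(self):
        D = random_D(m=15, n=6, seed=4)
        dec = cp.fit_components(D)
        resid = D - dec.components[:, :1] @ dec.coefficients[:, :1].T
        np.testing.assert_allclose(
            np.sum(resid**2), dec.eigenvalues[1:].sum(), rtol=1e-10)

    def test_zero_coefficients_give_zero_off_diagonal(self):
        D = random_D(m=15, n=6, seed=5)
        dec = cp.fit_components(D)
        dec.coefficients[2, :] = 0.0
        M = cp.subject_expansion(dec, 2, node_count=6)
        assert np.max(np.abs(cn.vectorize(M))) == 0.0


class TestCoefficientAgeCorrelations:
    def test_identity_coefficient_column(self):
        dec = cp.fit_components(random_D(m=30, n=10, seed=6))
        ages = np.linspace(20, 70, 10)
        dec.coefficients[:, 3] = ages
        table = cp.coefficient_age_correlations(dec, ages)
        top = table.iloc[0]
        assert top["component"] == 3
        assert top["r"] == pytest.approx(1.0)

    def test_orthogonal_coefficients_give_zero(self):
        dec = cp.fit_components(random_D(m=30, n=4, seed=7))
        ages = np.array([10.0, 20.0, 30.0, 40.0])
        dec.coefficients[:, 0] = [1.0, -1.0, -1.0, 1.0]  # orthogonal to centered ages
        table = cp.coefficient_age_correlations(dec, ages)
        r0 = float(table.loc[table["component"] == 0, "r"].iloc[0])
        assert r0 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_column_flagged(self):
        dec = cp.fit_components(random_D(m=30, n=5, seed=8))
        dec.coefficients[:, 1] = 2.0
        table = cp.coefficient_age_correlations(dec, np.arange(5.0))
        row = table.loc[table["component"] == 1].iloc[0]
        assert row["zero_variance"] and row["r"] == 0.0


class TestAgeEffectMatrix:
    def test_perfectly_linear_edges_give_unit_entries(self):
        ages = np.linspace(10, 80, 12)
        D = np.outer(np.full(10, 0.01), ages)
        M = cp.age_effect_matrix(D, ages, node_count=5)
        iu = np.triu_indices(5, k=1)
        np.testing.assert_allclose(M[iu], 1.0, atol=1e-12)
        np.testing.assert_array_equal(M, M.T)
        assert np.all(np.diag(M) == 1.0)

    def test_age_independent_edges_bounded_by_permutation_quantile(self, rng):
        """Null edges stay below the max-|r| quantile of an explicit
        permutation oracle at the same n."""
        n, m = 40, 190  # m = p(p-1)/2 for p = 20 nodes
        ages = np.linspace(10, 80, n)
        D = rng.normal(size=(m, n))
        vals = cp.age_effect_matrix(D, ages)
        iu = np.triu_indices(vals.shape[0], k=1)
        observed_max = np.abs(vals[iu]).max()
        # permutation oracle: max |r| distribution under shuffled ages
        maxes = []
        for _ in range(200):
            perm = rng.permutation(n)
            pm = cp.age_effect_matrix(D, ages[perm])
            maxes.append(np.abs(pm[np.triu_indices(pm.shape[0], k=1)]).max())
        assert observed_max <= np.quantile(maxes, 0.995)

    def test_constant_edge_recorded_as_zero(self):
        ages = np.arange(12.0)
        D = np.random.default_rng(0).normal(size=(3, 12))
        D[1] = 5.0
        M = cp.age_effect_matrix(D, ages, node_count=3)
        assert M[0, 2] == 0.0  # edge index 1 is the (0, 2) pair


class TestCompareMatrices:
    def test_identity_comparison(self):
        M = cn.devectorize(np.random.default_rng(3).normal(size=45), diag=1.0)
        rep = cp.compare_matrices(M, M)
        assert rep["r"] == pytest.approx(1.0)
        np.testing.assert_allclose(rep["linear"]["coefficients"], [0.0, 1.0], atol=1e-10)

    def test_sign_flip(self):
        M = cn.devectorize(np.random.default_rng(4).normal(size=45), diag=1.0)
        assert cp.compare_matrices(M, -M)["r"] == pytest.approx(-1.0)

    def test_exact_quadratic_fit(self):
        Ma = cn.devectorize(np.linspace(-1, 1, 15), node_count=6)
        a = cn.vectorize(Ma)
        Mb = cn.devectorize(a**2, node_count=6)
        rep = cp.compare_matrices(Ma, Mb)
        np.testing.assert_allclose(
            rep["quadratic"]["coefficients"], [0.0, 0.0, 1.0], atol=1e-10)

    def test_zero_variance_rejected(self):
        M = cn.devectorize(np.zeros(15), node_count=6)
        with pytest.raises(ValueError):
            cp.compare_matrices(M, M)


class TestComponentNetworkSummary:
    def test_constant_component(self, small_cohort):
        D = cn.build_cohort_matrix(small_cohort)
        dec = cp.fit_components(D.values)
        dec.edge_index = D.edge_index
        dec.components[:, 0] = 0.7
        summ = cp.component_network_summary(dec, 0, small_cohort.partition)
        sizes = small_cohort.partition["network"].value_counts()
        for net, v in summ["within"].items():
            if sizes[net] >= 2:
                assert v == pytest.approx(0.7)
            else:
                assert np.isnan(v)  # singleton network: within undefined
        for v in summ["between"].values():
            assert v == pytest.approx(0.7)

    def test_hand_computed_two_network_case(self):
        import pandas as pd

        partition = pd.DataFrame({
            "node_id": [0, 1, 2, 3],
            "network": ["A", "A", "B", "B"],
            "hemisphere": ["L", "R", "L", "R"],
        })
        vec = np.array([0.8, 0.2, 0.2, 0.2, 0.2, 0.5])  # edges 01,02,03,12,13,23
        dec = cp.ComponentDecomposition(
            components=vec[:, None], coefficients=np.ones((1, 1)),
            explained_variance=np.array([1.0]), eigenvalues=np.array([1.0]),
            edge_index=cn.edge_index_for(4))
        summ = cp.component_network_summary(dec, 0, partition)
        assert summ["within"]["A"] == pytest.approx(0.8)
        assert summ["within"]["B"] == pytest.approx(0.5)
        assert summ["between"][("A", "B")] == pytest.approx(0.2)

    def test_threshold_above_max_gives_empty_list(self, small_cohort):
        D = cn.build_cohort_matrix(small_cohort)
        dec = cp.fit_components(D.values)
        dec.edge_index = D.edge_index
        big = np.abs(dec.components[:, 0]).max() + 1
        summ = cp.component_network_summary(dec, 0, small_cohort.partition, threshold=big)
        assert summ["top_edges"] == []


class TestHemisphereChiSquare:
    def test_null_edge_set_gives_zero_statistic(self, small_cohort):
        # use every possible edge: observed proportions equal expected
        p = small_cohort.n_nodes
        edges = cn.edge_index_for(p)
        res = cp.hemisphere_chi_square(edges, small_cohort.partition)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_statistic(self):
        import pandas as pd

        # alternating hemispheres on 4 nodes -> 2 intra / 4 inter pairs is not
        # 50/50, so craft a partition whose global split is exactly half
        partition = pd.DataFrame({
            "node_id": range(4),
            "network": ["A"] * 4,
            "hemisphere": ["L", "L", "R", "R"],
        })
        # global pairs: intra {01, 23}=2, inter {02,03,12,13}=4 -> prop 1/3
        # craft edge set of 40 with observed 30 intra -> E = (40/3, 80/3)
        edges = [(0, 1)] * 30 + [(0, 2)] * 10
        res = cp.hemisphere_chi_square(edges, partition)
        e_intra, e_inter = 40 / 3, 80 / 3
        expect = (30 - e_intra) ** 2 / e_intra + (10 - e_inter) ** 2 / e_inter
        assert res["statistic"] == pytest.approx(expect, abs=1e-10)

    def test_empty_edge_set_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            cp.hemisphere_chi_square(np.empty((0, 2)), small_cohort.partition)
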