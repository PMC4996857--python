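"""PCA correctness, PC1 orientation, and the mean +/- 2SD selection rule."""

import numpy as np
import pandas as pd
import pytest

from cardiomat import (ExpressionMatrix, SampleTable, ValidationError,
                       orient_pc1, pca, select_maturation_genes)
from cardiomat.pca import PCAResult


def gene_matrix(arr, genes=None, **kw):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    kw.setdefault("feature_kind", "gene")
    return ExpressionMatrix(
        pd.DataFrame(arr, index=genes, columns=[f"s{j}" for j in range(arr.shape[1])]),
        **kw,
    )


def loading_result(loadings: dict[str, float]) -> PCAResult:
    """A minimal oriented PCA result carrying only PC1 loadings."""
    genes = list(loadings)
    lvec = np.asarray([loadings[g] for g in genes], dtype=float)
    return PCAResult(
        scores=pd.DataFrame({"PC1": [0.0, 1.0]}, index=["sa", "sb"]),
        loadings=pd.DataFrame({"PC1": lvec}, index=genes),
        explained_variance=np.array([1.0]),
    )


class TestPca:
    def test_rank_one_matrix_has_single_component(self):
        m = gene_matrix([[1, 2, 3], [2, 4, 6]])
        p = pca(m, 2, allow_unscaled=True)
        assert p.explained_variance[1] == pytest.approx(0.0, abs=1e-10)
        assert p.explained_variance[0] > 0

    def test_score_variance_equals_explained_variance(self):
        rng = np.random.default_rng(1)
        m = gene_matrix(rng.normal(size=(15, 8)))
        p = pca(m, 5, allow_unscaled=True)
        v = p.scores.to_numpy().var(axis=0, ddof=1)
        assert np.allclose(v, p.explained_variance, atol=1e-10)

    def test_loadings_orthonormal_and_scores_are_projections(self):
        rng = np.random.default_rng(2)
        m = gene_matrix(rng.normal(size=(12, 7)))
        p = pca(m, 6, allow_unscaled=True)
        L = p.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(6), atol=1e-8)
        X = m.values.to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        assert np.allclose(p.scores.to_numpy(), Xc.T @ L, atol=1e-8)

    def test_matches_covariance_eigendecomposition(self):
        """Loadings/scores agree with a brute-force eigendecomposition of the
        feature covariance matrix, up to column sign."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = gene_matrix(rng.normal(size=(10, 6)))
            p = pca(m, 5, allow_unscaled=True)
            X = m.values.to_numpy()
            Xc = X - X.mean(axis=1, keepdims=True)
            C = Xc @ Xc.T / (X.shape[1] - 1)
            w, V = np.linalg.eigh(C)
            order = np.argsort(w)[::-1]
            w, V = w[order], V[:, order]
            assert np.allclose(p.explained_variance, w[:5], atol=1e-8)
            for k in range(5):
                dot = abs(float(V[:, k] @ p.loadings.to_numpy()[:, k]))
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_requires_scaled_unless_waived(self):
        m = gene_matrix([[1, 2, 3], [4, 5, 7]])
        with pytest.raises(ValidationError, match="allow_unscaled"):
            pca(m, 1)

    def test_too_many_components_rejected(self):
        m = gene_matrix([[1, 2, 3], [4, 6, 5]])
        with pytest.raises(ValidationError, match="n_components"):
            pca(m, 3, allow_unscaled=True)


class TestOrientPc1:
    @pytest.fixture()
    def staged(self):
        rows = [{"sample_id": f"s{j}", "stage": j // 2 + 1,
                 "species": "m", "batch": "b"} for j in range(6)]
        return SampleTable(pd.DataFrame(rows))

    def make_result(self, staged, increasing=True):
        rng = np.random.default_rng(4)
        base = np.linspace(0, 5, 6) if increasing else np.linspace(5, 0, 6)
        m = gene_matrix(
            np.outer(rng.uniform(0.5, 1.5, 10), base) + rng.normal(0, 0.05, (10, 6))
        )
        return pca(m, 2, allow_unscaled=True)

    def test_oriented_result_unchanged(self, staged):
        p = orient_pc1(self.make_result(staged), staged)
        again = orient_pc1(p, staged)
        assert np.allclose(p.scores, again.scores)
        assert np.allclose(p.loadings, again.loadings)

    def test_negated_input_gives_same_orientation(self, staged):
        p = orient_pc1(self.make_result(staged), staged)
        p_neg = orient_pc1(self.make_result(staged).flipped(0), staged)
        assert np.allclose(p.scores, p_neg.scores)
        assert np.allclose(p.loadings, p_neg.loadings)

    def test_high_stage_scores_exceed_low_after_orientation(self, staged):
        for increasing in (True, False):
            p = orient_pc1(self.make_result(staged, increasing), staged)
            s = p.scores.iloc[:, 0].to_numpy()
            assert s[4:].mean() > s[:2].mean()

    def test_planted_increasing_genes_get_positive_loadings(self, small_config):
        from dataclasses import replace
        from cardiomat import simulate_mouse_pair
        cfg = replace(small_config, noise_sd=0.05, batch_sd=0.0)
        _, _, matrix_b, _, samples_b, truth = simulate_mouse_pair(cfg)
        p = orient_pc1(pca(matrix_b, 1, allow_unscaled=True), samples_b)
        pc1 = p.loadings.iloc[:, 0]
        for g in matrix_b.feature_ids:
            if truth.direction[g] == +1:
                assert pc1[g] > 0
            elif truth.direction[g] == -1:
                assert pc1[g] < 0


class TestSelection:
    def test_all_equal_loadings_select_nothing(self):
        pa = loading_result({f"g{i}": 0.2 for i in range(10)})
        pb = loading_result({f"g{i}": 0.2 for i in range(10)})
        table, sel = select_maturation_genes(pa, pb)
        assert sel.selected == set()

    def test_outlier_goes_to_matching_list(self):
        base = {f"g{i}": 0.01 * ((-1) ** i) for i in range(40)}
        pa = loading_result({**base, "hot": 0.9, "cold": -0.9})
        pb = loading_result({**base, "hot": 0.9, "cold": -0.9})
        table, sel = select_maturation_genes(pa, pb)
        assert "hot" in sel.mature and "cold" in sel.immature
        assert sel.provenance["hot"] == "shared"
        assert table.loc["hot", "summed"] == pytest.approx(1.8)

    def test_unique_pool_uses_platform_specific_threshold(self):
        shared = {f"g{i}": 0.01 * ((-1) ** i) for i in range(40)}
        pa = loading_result({**shared, "ua_hot": 0.8,
                             **{f"ua{i}": 0.005 * ((-1) ** i) for i in range(20)}})
        pb = loading_result(shared)
        _, sel = select_maturation_genes(pa, pb)
        assert "ua_hot" in sel.mature
        assert sel.provenance["ua_hot"] == "uniqueA"

    def test_platform_relabeling_symmetry(self):
        rng = np.random.default_rng(11)
        la = {f"g{i}": float(x) for i, x in enumerate(rng.normal(0, 0.1, 60))}
        lb = {f"g{i}": float(x) for i, x in enumerate(rng.normal(0, 0.1, 60))}
        lb.update({f"ub{i}": float(x) for i, x in enumerate(rng.normal(0, 0.1, 10))})
        _, s_ab = select_maturation_genes(loading_result(la), loading_result(lb))
        _, s_ba = select_maturation_genes(loading_result(lb), loading_result(la))
        assert s_ab.mature == s_ba.mature
        assert s_ab.immature == s_ba.immature

    def test_mature_loadings_exceed_immature_within_pool(self):
        rng = np.random.default_rng(13)
        la = {f"g{i}": float(x) for i, x in enumerate(rng.normal(0, 0.1, 500))}
        lb = {f"g{i}": float(x) for i, x in enumerate(rng.normal(0, 0.1, 500))}
        table, sel = select_maturation_genes(loading_result(la), loading_result(lb))
        if sel.mature and sel.immature:
            summed = table["summed"]
            assert summed[list(sel.mature)].min() > summed[list(sel.immature)].max()

    def test_empty_everything_rejected(self):
        empty = PCAResult(
            scores=pd.DataFrame({"PC1": []}),
            loadings=pd.DataFrame({"PC1": []}),
            explained_variance=np.array([0.0]),
        )
        with pytest.raises(ValidationError, match="empty"):
            select_maturation_genes(empty, empty)
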