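"""Feature selection, transforms, Varimax PCA, GMM, MFA, consensus, MCC."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tamont
from tamont import preprocess as pp
from tamont import signature as sig

from conftest import make_counts


def cpm_adata(X, genes=None, platforms=None):
    a = ad.AnnData(X=np.asarray(X, float))
    if genes is not None:
        a.var_names = genes
    a.obs["platform"] = platforms if platforms is not None else ["C1"] * a.n_obs
    a.uns["scale"] = "cpm"
    return a


class TestSelectHomologueFeatures:
    def _inputs(self):
        mouse = pd.DataFrame(
            {
                "mouse_gene": ["mmA", "mmB", "mmC"],
                "lineage": [tamont.BLOOD, tamont.MICROGLIA, tamont.BLOOD],
                "dual_model": [True, True, True],
            }
        )
        homology = pd.DataFrame(
            {"mouse_gene": ["mmA", "mmB"], "human_gene": ["A", "B"]}
        )
        return mouse, homology

    def test_mean_cpm_threshold_strict(self):
        mouse, homology = self._inputs()
        expr = cpm_adata([[2.0, 1.0, 50.0], [2.0, 1.0, 50.0]], genes=["A", "B", "C"])
        out = sig.select_homologue_features(expr, mouse, homology)
        assert out == ["A"]  # B at exactly 1.0 dropped; C unmapped

    def test_empty_result_is_diagnostic_error(self):
        mouse, homology = self._inputs()
        expr = cpm_adata([[0.5, 0.5, 50.0]], genes=["A", "B", "C"])
        with pytest.raises(ValueError, match="mapped homologues"):
            sig.select_homologue_features(expr, mouse, homology)

    def test_recovers_candidate_pool(self, small_study, small_pipeline):
        assert len(small_pipeline.candidates) == small_study.config.n_candidate_genes


class TestLogTransform:
    def test_fixed_points(self):
        expr = cpm_adata([[0.0, 10.0, 70.0]])
        out = sig.log_transform(expr)
        np.testing.assert_allclose(np.asarray(out.X)[0], [0.0, 1.0, 3.0])
        assert out.uns["scale"] == "logcpm"

    def test_negative_input_rejected(self):
        expr = cpm_adata([[-1.0]])
        with pytest.raises(ValueError):
            sig.log_transform(expr)


class TestZscoreByPlatform:
    def _expr(self, X, platforms):
        a = cpm_adata(X, platforms=platforms)
        a.uns["scale"] = "logcpm"
        return a

    def test_within_platform_moments(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 2, (40, 6))
        z = sig.zscore_by_platform(self._expr(X, ["C1"] * 20 + ["SmartSeq2"] * 20))
        Z = np.asarray(z.X)
        for m in (slice(0, 20), slice(20, 40)):
            np.testing.assert_allclose(Z[m].mean(axis=0), 0.0, atol=1e-10)
            np.testing.assert_allclose(Z[m].std(axis=0), 1.0, atol=1e-10)

    def test_constant_gene_zeroed_and_flagged(self):
        X = np.ones((6, 2))
        X[:, 1] = [1, 2, 3, 4, 5, 6]
        z = sig.zscore_by_platform(self._expr(X, ["C1"] * 6))
        assert np.asarray(z.X)[:, 0].tolist() == [0.0] * 6
        assert z.uns["constant_genes"]

    def test_platform_offsets_absorbed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (30, 5))
        plats = ["C1"] * 15 + ["SmartSeq2"] * 15
        z1 = sig.zscore_by_platform(self._expr(X, plats))
        shifted = X.copy()
        shifted[:15] += 3.0  # constant per-platform offset on every gene
        z2 = sig.zscore_by_platform(self._expr(shifted, plats))
        np.testing.assert_allclose(np.asarray(z1.X), np.asarray(z2.X), atol=1e-10)

    def test_single_cell_platform_error(self):
        with pytest.raises(ValueError):
            sig.zscore_by_platform(self._expr(np.ones((3, 2)), ["C1", "C1", "SmartSeq2"]))


class TestPcaVarimax:
    def test_two_anticorrelated_genes_analytic(self):
        t = np.linspace(-1, 1, 50)
        t = (t - t.mean()) / t.std(ddof=1)  # standardized, as in the pipeline
        X = np.column_stack([t, -t])
        res = sig.pca_varimax(X, genes=["up", "down"], n_components=2)
        # one component carries all variance; loadings are unit correlations
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(np.abs(res.loadings.iloc[:, 0]), [1.0, 1.0], atol=1e-10)

    def test_rotation_orthogonal(self, small_pipeline):
        R = small_pipeline.pca.rotation
        err = np.abs(R.T @ R - np.eye(R.shape[1])).max()
        assert err < 1e-8

    def test_rotation_preserves_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (50, 20))
        res = sig.pca_varimax(X, n_components=5)
        # rotated standardized scores times rotated loadings = rank-k
        # reconstruction of the unrotated solution
        rot = res.scores.to_numpy() @ res.loadings.to_numpy().T
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        recon = U[:, :5] * s[:5] @ Vt[:5]
        np.testing.assert_allclose(rot, recon, atol=1e-8)

    def test_varimax_criterion_not_below_unrotated(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (60, 15))
        res = sig.pca_varimax(X, n_components=4)
        before = sig.varimax_criterion(res.unrotated_loadings.to_numpy())
        after = sig.varimax_criterion(res.loadings.to_numpy())
        assert after >= before - 1e-12

    def test_rank_deficiency_reduces_components(self):
        X = np.outer(np.arange(10.0), np.ones(6))  # rank 1 after centering
        with pytest.warns(UserWarning, match="rank"):
            res = sig.pca_varimax(X, n_components=5)
        assert res.loadings.shape[1] == 1


class TestGmm1d:
    def test_separated_components_recovered(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-3, 1, 100), rng.normal(3, 1, 100)])
        truth = np.array([0] * 100 + [1] * 100)
        fit = sig.fit_gmm_1d(x, seed=5)
        assert sig.matthews_correlation(fit.labels, truth) >= 0.95
        assert fit.overlap < 0.05

    def test_coincident_components_overlap_half(self):
        assert sig.gmm_overlap([0.5, 0.5], [0.0, 0.0], [1.0, 1.0]) == pytest.approx(
            0.5, abs=1e-8
        )

    def test_two_points_get_own_components(self):
        fit = sig.fit_gmm_1d(np.array([-1.0, 1.0]), seed=0)
        assert set(fit.labels) == {0, 1}

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sig.fit_gmm_1d(np.array([0.0, np.nan, 1.0]))


class TestExtractSignature:
    def _pca_with_loadings(self, loadings: pd.Series) -> sig.PCAResult:
        L = loadings.to_frame("PC1")
        return sig.PCAResult(
            genes=list(loadings.index), cells=[], loadings=L,
            scores=pd.DataFrame(columns=["PC1"]), rotation=np.eye(1),
            explained_variance=np.array([1.0]),
            explained_variance_ratio=np.array([1.0]),
            unrotated_loadings=L, unrotated_scores=pd.DataFrame(columns=["PC1"]),
        )

    def _tables(self, genes, lineages):
        mouse = pd.DataFrame(
            {"mouse_gene": [f"mm{g}" for g in genes], "lineage": lineages,
             "dual_model": True}
        )
        hom = pd.DataFrame({"mouse_gene": [f"mm{g}" for g in genes], "human_gene": genes})
        return mouse, hom

    def test_threshold_strict_and_orientation(self):
        genes = [f"g{i}" for i in range(20)]
        lineages = [tamont.BLOOD] * 10 + [tamont.MICROGLIA] * 10
        loadings = pd.Series([0.5] * 9 + [0.20] + [-0.5] * 9 + [-0.20], index=genes)
        mouse, hom = self._tables(genes, lineages)
        s = sig.extract_signature(self._pca_with_loadings(loadings), mouse, hom)
        assert len(s.genes) == 18  # the two genes at exactly 0.20 excluded
        assert s.blood_sign == 1
        assert set(s.lineage_genes(tamont.BLOOD)) == set(genes[:9])
        assert set(s.lineage_genes(tamont.MICROGLIA)) == set(genes[10:19])

    def test_inverted_axis_oriented_by_enrichment(self):
        genes = [f"g{i}" for i in range(20)]
        lineages = [tamont.BLOOD] * 10 + [tamont.MICROGLIA] * 10
        loadings = pd.Series([-0.5] * 10 + [0.5] * 10, index=genes)
        mouse, hom = self._tables(genes, lineages)
        s = sig.extract_signature(self._pca_with_loadings(loadings), mouse, hom)
        assert s.blood_sign == -1
        assert set(s.lineage_genes(tamont.BLOOD)) == set(genes[:10])

    def test_no_passing_gene_is_error(self):
        genes = ["a", "b"]
        mouse, hom = self._tables(genes, [tamont.BLOOD, tamont.MICROGLIA])
        loadings = pd.Series([0.1, -0.1], index=genes)
        with pytest.raises(ValueError, match="no gene passes"):
            sig.extract_signature(self._pca_with_loadings(loadings), mouse, hom)

    def test_ambiguous_orientation_is_error(self):
        genes = [f"g{i}" for i in range(8)]
        lineages = [tamont.BLOOD, tamont.MICROGLIA] * 4
        loadings = pd.Series([0.5, 0.5, -0.5, -0.5] * 2, index=genes)
        mouse, hom = self._tables(genes, lineages)
        with pytest.raises(ValueError, match="ambiguous"):
            sig.extract_signature(self._pca_with_loadings(loadings), mouse, hom)


class TestLineageEnrichment:
    def _run(self, a, b, c, d):
        genes = [f"g{i}" for i in range(a + b + c + d)]
        lineages = ([tamont.BLOOD] * a + [tamont.MICROGLIA] * b
                    + [tamont.BLOOD] * c + [tamont.MICROGLIA] * d)
        loadings = pd.Series([0.4] * (a + b) + [-0.4] * (c + d), index=genes)
        mouse = pd.DataFrame({"mouse_gene": genes, "lineage": lineages, "dual_model": True})
        hom = pd.DataFrame({"mouse_gene": genes, "human_gene": genes})
        return sig.lineage_enrichment_test(loadings, mouse, hom)

    def test_perfect_association_matches_enumeration(self):
        res = self._run(10, 0, 0, 10)
        # hypergeometric oracle: only the observed and mirror table are as extreme
        p_oracle = 2 * stats.hypergeom.pmf(10, 20, 10, 10)
        assert res.p.iloc[0] == pytest.approx(p_oracle, rel=1e-12)
        assert np.isinf(res.odds_ratio.loc["positive"])

    def test_independent_margins(self):
        res = self._run(5, 5, 5, 5)
        assert res.p.iloc[0] == pytest.approx(1.0)
        assert res.odds_ratio.loc["positive"] == pytest.approx(1.0)

    def test_row_swap_symmetry(self):
        assert self._run(8, 2, 3, 7).p.iloc[0] == pytest.approx(
            self._run(3, 7, 8, 2).p.iloc[0], rel=1e-12
        )


class TestMfa:
    def _table(self, seed=0, n=40, p=12):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, p))
        return pd.DataFrame(X, index=[f"c{i}" for i in range(n)],
                            columns=[f"g{j}" for j in range(p)])

    def test_duplicated_table_ratio_one(self):
        t = self._table()
        res = sig.mfa_combine([t, t])
        assert res.ratio == pytest.approx(1.0, abs=1e-8)

    def test_global_rescale_cancels(self):
        t = self._table(1)
        res = sig.mfa_combine([t, 3.0 * t])
        assert res.ratio == pytest.approx(1.0, abs=1e-8)

    def test_single_table_is_plain_pca(self):
        t = self._table(2)
        res = sig.mfa_combine([t])
        pca = sig.pca_varimax(t.to_numpy(), genes=list(t.columns),
                              n_components=res.scores.shape[1])
        k = pca.unrotated_scores.shape[1]
        np.testing.assert_allclose(
            res.scores.to_numpy()[:, :k] * np.linalg.svd(t.to_numpy(), compute_uv=False)[0],
            pca.unrotated_scores.to_numpy(),
            atol=1e-8,
        )

    def test_disjoint_gene_sets_error(self):
        t1 = self._table(3)
        t2 = self._table(4).rename(columns=lambda c: "x" + c)
        with pytest.raises(ValueError, match="share no genes"):
            sig.mfa_combine([t1, t2])


class TestConsensusCluster:
    def _blobs(self, n_per=40, p=10, sep=6.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(-sep / 2, 1, (n_per, p))
        b = rng.normal(sep / 2, 1, (n_per, p))
        return np.vstack([a, b]), np.array([0] * n_per + [1] * n_per)

    def test_separated_blobs_recovered(self):
        X, truth = self._blobs()
        res = sig.consensus_cluster(X, k=2, seed=0)
        assert sig.matthews_correlation(res.labels, truth) >= 0.95

    def test_duplicated_cells_get_duplicated_labels(self):
        X, _ = self._blobs(n_per=25)
        res = sig.consensus_cluster(np.vstack([X, X]), k=2, seed=1)
        lab = res.labels.to_numpy()
        assert (lab[: len(X)] == lab[len(X):]).all()

    def test_constant_matrix_error(self):
        with pytest.raises(ValueError):
            sig.consensus_cluster(np.ones((20, 5)), k=2, seed=0)

    def test_deterministic_given_seed(self):
        X, _ = self._blobs(seed=2)
        a = sig.consensus_cluster(X, k=2, seed=3).labels
        b = sig.consensus_cluster(X, k=2, seed=3).labels
        assert (a == b).all()


class TestMatthewsCorrelation:
    def test_identical_and_inverted(self):
        a = np.array([0, 0, 1, 1, 0, 1])
        assert sig.matthews_correlation(a, a) == pytest.approx(1.0)
        assert sig.matthews_correlation(a, 1 - a) == pytest.approx(1.0)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert sig.matthews_correlation(a, b) < 0.05

    def test_degenerate_single_class(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert sig.matthews_correlation(np.zeros(5), np.array([0, 1, 0, 1, 0])) == 0.0


class TestPipeline:
    def test_fixed_seed_identical_signature(self, small_study, small_preprocessed):
        tam = small_preprocessed.counts[
            small_preprocessed.annotation.cell_class == pp.TAM
        ].copy()
        a = sig.derive_signature(tam, small_study.mouse_table, small_study.homology, seed=7)
        b = sig.derive_signature(tam, small_study.mouse_table, small_study.homology, seed=7)
        pd.testing.assert_frame_equal(a.signature.entries, b.signature.entries)

    def test_null_effect_gives_uninformative_partition(self):
        """With no planted lineage effect the GMM split carries no
        information about the (arbitrary) truth labels."""
        mccs = []
        for seed in range(8):
            cfg = tamont.SimulationConfig(
                n_samples=4, n_cells_per_sample=100, n_genes=600,
                n_candidate_genes=100, n_true_signature=30, effect_size=0.0,
                neoplastic_fraction=0.0, n_cnv_segments=0, n_variants=0,
                seed=100 + seed,
            )
            study = tamont.simulate_study(cfg)
            cpm = pp.cpm_normalize(study.counts)
            cands = sig.select_homologue_features(cpm, study.mouse_table, study.homology)
            z = sig.zscore_by_platform(sig.log_transform(cpm))
            pca = sig.pca_varimax(z, cands)
            fit = sig.fit_gmm_1d(pca.pc1_scores.to_numpy(), seed=seed)
            truth = (study.truth.cell_lineage.reindex(pca.cells) == tamont.BLOOD)
            mccs.append(sig.matthews_correlation(fit.labels, truth.astype(int)))
        assert np.mean(mccs) < 0.2

    def test_platform_offset_changes_no_assignment(self, small_study, small_preprocessed):
        """Per-platform z-scoring absorbs constant per-platform offsets."""
        res = small_preprocessed
        tam_mask = (res.annotation.cell_class == pp.TAM).to_numpy()
        cpm = pp.cpm_normalize(res.counts[tam_mask].copy())
        cands = sig.select_homologue_features(cpm, small_study.mouse_table,
                                              small_study.homology)
        logx = sig.log_transform(cpm)
        z1 = sig.zscore_by_platform(logx)
        shifted = logx.copy()
        offset = (shifted.obs.platform == "C1").to_numpy().astype(float) * 2.5
        shifted.X = np.asarray(shifted.X) + offset[:, None]
        shifted.uns["scale"] = "logcpm"
        z2 = sig.zscore_by_platform(shifted)
        p1 = sig.pca_varimax(z1, cands)
        p2 = sig.pca_varimax(z2, cands)
        f1 = sig.fit_gmm_1d(p1.pc1_scores.to_numpy(), seed=1)
        f2 = sig.fit_gmm_1d(p2.pc1_scores.to_numpy(), seed=1)
        assert sig.matthews_correlation(f1.labels, f2.labels) == pytest.approx(1.0)
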