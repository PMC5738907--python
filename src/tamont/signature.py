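"""Derivation of the TAM ontogeny signature.

The lineage signature separating blood-derived from microglial TAMs is
derived in five steps: (1) feature selection — human homologues of genes
that are lineage-specific in murine glioma models, restricted to genes
expressed in the human TAMs (mean CPM > 1); (2) transformation —
log2(CPM/10 + 1) followed by per-gene z-scoring within each capture
platform, which absorbs platform-level offsets; (3) PCA with Varimax
rotation in the candidate-gene space — the first rotated component (PC1)
is the ontogeny axis; (4) partitioning of PC1 scores with a two-component
Gaussian mixture; (5) extraction of genes with |PC1 loading| > 0.2, with
the sign direction oriented to lineage by a Fisher enrichment test against
the murine lineage labels. Loadings are on the component-correlation scale
(eigenvector times the component's singular value over sqrt(n-1)), the
scale on which a fixed 0.2 threshold is meaningful.

Two independent cross-checks of the partition are also implemented:
multiple factor analysis (MFA) to combine the per-platform tables with
balanced inertia, and an SC3-style consensus clustering whose agreement
with the GMM partition is summarized by the Matthews correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import fisher_exact, norm, rankdata
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .simulate import BLOOD, MICROGLIA


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


# ---------------------------------------------------------------------------
# feature selection and transforms
# ---------------------------------------------------------------------------

def dual_model_human_genes(mouse_table: pd.DataFrame, homology: pd.DataFrame) -> pd.DataFrame:
    """Human homologues of dual-model murine lineage genes, with their
    murine lineage label. Returns columns ``human_gene, lineage``."""
    dual = mouse_table[mouse_table.dual_model]
    merged = dual.merge(homology, on="mouse_gene", how="inner")
    return merged[["human_gene", "lineage"]].drop_duplicates("human_gene")


def select_homologue_features(
    expr: ad.AnnData,
    mouse_table: pd.DataFrame,
    homology: pd.DataFrame,
    min_mean_cpm: float = 1.0,
) -> list[str]:
    """Candidate genes: mapped homologues of dual-model murine lineage genes
    with mean expression strictly above ``min_mean_cpm`` in the matrix.

    ``expr`` must be on the CPM scale. Raises with per-step diagnostics if
    no gene survives the funnel.
    """
    if expr.uns.get("scale") != "cpm":
        raise ValueError("select_homologue_features expects CPM-scale expression")
    mapped = dual_model_human_genes(mouse_table, homology)
    in_matrix = [g for g in mapped.human_gene if g in expr.var_names]
    if in_matrix:
        X = _dense(expr[:, in_matrix].X)
        means = X.mean(axis=0)
        selected = [g for g, m in zip(in_matrix, means) if m > min_mean_cpm]
    else:
        selected = []
    if not selected:
        n_dual = int(mouse_table.dual_model.sum())
        raise ValueError(
            "no candidate genes survive the homologue filter "
            f"(dual-model mouse genes: {n_dual}; mapped homologues: {len(mapped)}; "
            f"present in matrix: {len(in_matrix)}; mean CPM > {min_mean_cpm}: 0)"
        )
    # preserve matrix gene order
    sel = set(selected)
    return [g for g in expr.var_names if g in sel]


def log_transform(expr: ad.AnnData) -> ad.AnnData:
    """log2(CPM/10 + 1) transform; zero-preserving and monotone."""
    if expr.uns.get("scale") != "cpm":
        raise ValueError("log_transform expects CPM-scale expression")
    X = _dense(expr.X)
    if (X < 0).any():
        raise ValueError("negative expression values")
    out = ad.AnnData(X=np.log2(X / 10.0 + 1.0), obs=expr.obs.copy(), var=expr.var.copy())
    out.uns["scale"] = "logcpm"
    return out


def zscore_by_platform(expr: ad.AnnData, platforms: pd.Series | None = None) -> ad.AnnData:
    """Z-score each gene across cells, within each capture platform
    independently. Genes constant within a platform are set to zero there
    and recorded in ``uns['constant_genes']``."""
    if expr.uns.get("scale") not in {"logcpm", "log"}:
        raise ValueError("zscore_by_platform expects log-scale expression")
    if platforms is None:
        platforms = expr.obs["platform"]
    platforms = pd.Series(np.asarray(platforms), index=expr.obs_names)
    X = _dense(expr.X).astype(float).copy()
    flagged: set[str] = set()
    for plat, idx in platforms.groupby(platforms).groups.items():
        mask = platforms.index.isin(idx)
        if mask.sum() < 2:
            raise ValueError(f"platform {plat!r} has fewer than 2 cells")
        sub = X[mask]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)
        zero_sd = sd == 0
        sd[zero_sd] = 1.0
        X[mask] = (sub - mu) / sd
        X[np.ix_(mask, zero_sd)] = 0.0
        flagged.update(np.asarray(expr.var_names)[zero_sd])
    out = ad.AnnData(X=X, obs=expr.obs.copy(), var=expr.var.copy())
    out.uns["scale"] = "zscore"
    out.uns["constant_genes"] = sorted(flagged)
    return out


# ---------------------------------------------------------------------------
# PCA with Varimax rotation
# ---------------------------------------------------------------------------

def varimax_rotation(
    loadings: np.ndarray,
    kaiser: bool = True,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> np.ndarray:
    """Orthogonal Varimax rotation matrix for a loadings matrix.

    Kaiser row normalization is applied during the iteration (rows with a
    zero communality are left as-is); the returned matrix is orthogonal.
    """
    p, k = loadings.shape
    if k < 2:
        return np.eye(k)
    A = loadings.copy()
    if kaiser:
        h = np.sqrt((A**2).sum(axis=1))
        h[h == 0] = 1.0
        A = A / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        B = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    return R


def varimax_criterion(loadings: np.ndarray, kaiser: bool = True) -> float:
    """Varimax objective: the summed per-component variance of squared
    (optionally Kaiser-normalized) loadings."""
    A = np.asarray(loadings, float)
    if kaiser:
        h = np.sqrt((A**2).sum(axis=1))
        h[h == 0] = 1.0
        A = A / h[:, None]
    sq = A**2
    return float(sq.var(axis=0).sum())


@dataclass
class PCAResult:
    """Varimax-rotated PCA of cells in a candidate-gene space.

    ``loadings`` are component correlations (genes x components, rotated);
    ``scores`` are standardized rotated cell scores. The pre-rotation
    solution is retained for reconstruction checks and MFA comparisons.
    """

    genes: list[str]
    cells: list[str]
    loadings: pd.DataFrame
    scores: pd.DataFrame
    rotation: np.ndarray
    explained_variance: np.ndarray  # SS of rotated loadings per component
    explained_variance_ratio: np.ndarray
    unrotated_loadings: pd.DataFrame
    unrotated_scores: pd.DataFrame  # raw projections (U * s), pre-rotation

    @property
    def pc1_loadings(self) -> pd.Series:
        return self.loadings.iloc[:, 0]

    @property
    def pc1_scores(self) -> pd.Series:
        return self.scores.iloc[:, 0]


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Sign convention: flip each column so its largest-|value| entry is
    positive. Returns the vector of flips (+/-1)."""
    idx = np.abs(V).argmax(axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def pca_varimax(
    expr: ad.AnnData | np.ndarray,
    genes: list[str] | None = None,
    n_components: int = 10,
) -> PCAResult:
    """PCA followed by Varimax rotation, restricted to ``genes``.

    Components are ordered by post-rotation explained variance and
    sign-fixed so the largest-|loading| gene of each component loads
    positively; lineage orientation is decided later by the enrichment
    test, never by this convention. If the matrix rank is below
    ``n_components`` the component count is reduced with a warning.
    """
    if isinstance(expr, ad.AnnData):
        sub = expr[:, genes] if genes is not None else expr
        X = _dense(sub.X).astype(float)
        gene_names = list(sub.var_names)
        cell_names = list(sub.obs_names)
    else:
        X = np.asarray(expr, float)
        gene_names = list(genes) if genes is not None else [f"g{i}" for i in range(X.shape[1])]
        cell_names = [f"c{i}" for i in range(X.shape[0])]
    n, p = X.shape
    if n_components >= min(n, p):
        n_components = min(n, p) - 1 or 1
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(f"matrix rank {rank} below requested components; using {k}")
    if k == 0:
        raise ValueError("degenerate (zero-variance) expression matrix")

    U, s, V = U[:, :k], s[:k], Vt[:k].T
    flips = _fix_signs(V)
    V = V * flips
    U = U * flips
    denom = np.sqrt(max(n - 1, 1))
    load_un = V * (s / denom)  # gene-component correlations for z-scored data
    scores_std = U * denom  # standardized scores (unit variance per comp)
    raw_scores = U * s  # plain projections X V

    R = varimax_rotation(load_un)
    L = load_un @ R
    F = scores_std @ R
    ss = (L**2).sum(axis=0)
    order = np.argsort(-ss)
    L, F, R, ss = L[:, order], F[:, order], R[:, order], ss[order]
    flips2 = _fix_signs(L)
    L, F, R = L * flips2, F * flips2, R * flips2

    comp = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        genes=gene_names,
        cells=cell_names,
        loadings=pd.DataFrame(L, index=gene_names, columns=comp),
        scores=pd.DataFrame(F, index=cell_names, columns=comp),
        rotation=R,
        explained_variance=ss,
        explained_variance_ratio=ss / p,
        unrotated_loadings=pd.DataFrame(load_un, index=gene_names, columns=comp),
        unrotated_scores=pd.DataFrame(raw_scores, index=cell_names, columns=comp),
    )


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture
# ---------------------------------------------------------------------------

@dataclass
class GMMFit:
    """Two-component 1-D Gaussian mixture fit of PC1 scores.

    ``overlap`` is the shared probability mass of the two weighted
    densities, the integral of min(pi1*phi1, pi2*phi2). Components are
    ordered by increasing mean."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    posteriors: np.ndarray  # n x k
    labels: np.ndarray  # argmax posterior
    overlap: float
    log_likelihood: float


def gmm_overlap(weights, means, sds, n_grid: int = 20001) -> float:
    """Overlap mass of a two-component 1-D Gaussian mixture by quadrature
    over mean +/- 8 SD."""
    weights = np.asarray(weights, float)
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    lo = float((means - 8 * sds).min())
    hi = float((means + 8 * sds).max())
    x = np.linspace(lo, hi, n_grid)
    dens = weights[:, None] * norm.pdf(x[None, :], means[:, None], sds[:, None])
    return float(np.trapezoid(dens.min(axis=0), x))


def fit_gmm_1d(
    scores,
    k: int = 2,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_init: int = 10,
    reg_covar: float = 1e-6,
) -> GMMFit:
    """EM fit of a k-component 1-D Gaussian mixture with k-means-seeded
    restarts; the best-likelihood solution is kept. The variance floor
    ``reg_covar`` prevents component collapse on near-duplicate points."""
    x = np.asarray(scores, float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite scores")
    if x.size < k:
        raise ValueError(f"need at least {k} values")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        tol=tol,
        max_iter=max_iter,
        n_init=n_init,
        init_params="kmeans",
        reg_covar=reg_covar,
        random_state=int(seed) % (2**31),
    )
    gm.fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    variances = gm.covariances_.reshape(-1)[order]
    wts = gm.weights_[order]
    post = gm.predict_proba(x[:, None])[:, order]
    labels = post.argmax(axis=1)
    overlap = gmm_overlap(wts, means, np.sqrt(variances)) if k == 2 else float("nan")
    return GMMFit(
        means=means,
        variances=variances,
        weights=wts,
        posteriors=post,
        labels=labels,
        overlap=overlap,
        log_likelihood=float(gm.score(x[:, None]) * x.size),
    )


# ---------------------------------------------------------------------------
# signature extraction and enrichment orientation
# ---------------------------------------------------------------------------

@dataclass
class SignatureGeneSet:
    """The derived lineage signature: genes with |PC1 loading| above the
    threshold, labeled blood-derived or microglial by the enrichment-
    oriented loading sign."""

    entries: pd.DataFrame  # columns: gene, lineage, loading
    threshold: float
    enrichment_p: float
    blood_sign: int  # +1 if positive loadings are blood-derived

    @property
    def genes(self) -> list[str]:
        return list(self.entries.gene)

    def lineage_genes(self, lineage: str) -> list[str]:
        return list(self.entries.gene[self.entries.lineage == lineage])

    def as_frame(self) -> pd.DataFrame:
        return self.entries.copy()


def lineage_enrichment_test(
    loadings: pd.Series,
    mouse_table: pd.DataFrame,
    homology: pd.DataFrame,
) -> pd.DataFrame:
    """Fisher's exact test of association between PC1 loading sign and
    murine lineage.

    Builds the 2x2 table (loading sign x mouse lineage) over genes with a
    known murine lineage and returns, per sign direction, the odds ratio
    for blood-lineage enrichment and the (shared) two-sided p value.
    Infinite odds ratios from empty cells are flagged, not corrected.
    """
    lin = dual_model_human_genes(mouse_table, homology).set_index("human_gene").lineage
    common = [g for g in loadings.index if g in lin.index]
    if not common:
        raise ValueError("no loaded gene has a murine lineage label")
    load = loadings.loc[common]
    labels = lin.loc[common]
    pos = load > 0
    a = int(((labels == BLOOD) & pos).sum())
    b = int(((labels == MICROGLIA) & pos).sum())
    c = int(((labels == BLOOD) & ~pos).sum())
    d = int(((labels == MICROGLIA) & ~pos).sum())
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate margin in lineage enrichment table")
        p = float("nan")
        or_pos = float("inf") if b * c == 0 else (a * d) / (b * c)
    else:
        or_pos, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    with np.errstate(divide="ignore"):
        or_neg = float("inf") if or_pos == 0 else 1.0 / or_pos
    out = pd.DataFrame(
        {"odds_ratio": [or_pos, or_neg], "p": [p, p]},
        index=["positive", "negative"],
    )
    out.attrs["table"] = {"a": a, "b": b, "c": c, "d": d}
    return out


def extract_signature(
    pca: PCAResult,
    mouse_table: pd.DataFrame,
    homology: pd.DataFrame,
    threshold: float = 0.2,
    max_orientation_p: float = 0.1,
) -> SignatureGeneSet:
    """Extract the signature: genes with |PC1 loading| strictly above the
    threshold, oriented to lineage by murine-marker enrichment.

    The sign direction enriched for murine blood-derived markers is
    labeled blood-derived; the opposite direction microglial. If the
    enrichment is ambiguous (p > ``max_orientation_p``) no orientation can
    be assigned and an error is raised.
    """
    load = pca.pc1_loadings
    passing = load[np.abs(load) > threshold]
    if passing.empty:
        raise ValueError(f"no gene passes |loading| > {threshold}")
    enr = lineage_enrichment_test(load, mouse_table, homology)
    p = float(enr.p.iloc[0])
    or_pos = float(enr.odds_ratio.loc["positive"])
    if not np.isfinite(p) or p > max_orientation_p:
        raise ValueError(
            f"signature orientation ambiguous (enrichment p = {p:.3g})"
        )
    blood_sign = 1 if or_pos > 1 else -1
    lineage = np.where(np.sign(passing) == blood_sign, BLOOD, MICROGLIA)
    entries = pd.DataFrame(
        {"gene": passing.index, "lineage": lineage, "loading": passing.to_numpy()}
    ).reset_index(drop=True)
    return SignatureGeneSet(
        entries=entries, threshold=threshold, enrichment_p=p, blood_sign=blood_sign
    )


# ---------------------------------------------------------------------------
# multiple factor analysis
# ---------------------------------------------------------------------------

@dataclass
class MFAResult:
    """Multi-table PCA with per-table first-singular-value scaling.

    ``partial_inertias[t]`` is the share of the combined solution's inertia
    carried by table ``t`` (the summed squared scores of its cells over the
    retained components); ``ratio`` is table1/table2."""

    scaling_factors: np.ndarray
    scores: pd.DataFrame
    loadings: pd.DataFrame
    partial_inertias: np.ndarray
    ratio: float
    table_of_cell: pd.Series


def mfa_combine(
    tables: list[ad.AnnData | pd.DataFrame],
    genes: list[str] | None = None,
    n_components: int | None = None,
) -> MFAResult:
    """Combine expression tables (cells x genes, z scale) by MFA.

    Each table is divided by its first singular value so no single table
    dominates, the scaled tables are stacked over cells, and a PCA of the
    stack yields combined scores/loadings and per-table partial inertias.
    """
    if len(tables) < 1:
        raise ValueError("need at least one table")
    frames = []
    for t, tab in enumerate(tables):
        if isinstance(tab, ad.AnnData):
            df = pd.DataFrame(_dense(tab.X), index=tab.obs_names, columns=tab.var_names)
        else:
            df = tab
        frames.append(df)
    if genes is None:
        genes = list(frames[0].columns)
        for df in frames[1:]:
            genes = [g for g in genes if g in df.columns]
    if not genes:
        raise ValueError("tables share no genes")

    mats, table_of_cell, cell_names, sfs = [], [], [], []
    for t, df in enumerate(frames):
        M = df[genes].to_numpy(float)
        s1 = np.linalg.svd(M, compute_uv=False)[0]
        if s1 == 0:
            raise ValueError(f"table {t} is identically zero")
        mats.append(M / s1)
        sfs.append(s1)
        names = [f"t{t}:{c}" for c in df.index]
        cell_names.extend(names)
        table_of_cell.extend([t] * len(df))
    Z = np.vstack(mats)
    Zc = Z - Z.mean(axis=0)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    k = rank if n_components is None else min(n_components, rank)
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    flips = _fix_signs(V)
    V, U = V * flips, U * flips
    scores = U * s

    table_idx = np.asarray(table_of_cell)
    inertias = np.array([
        float((scores[table_idx == t] ** 2).sum()) for t in range(len(frames))
    ])
    ratio = float(inertias[0] / inertias[1]) if len(frames) >= 2 else 1.0
    comp = [f"PC{i + 1}" for i in range(k)]
    return MFAResult(
        scaling_factors=np.asarray(sfs),
        scores=pd.DataFrame(scores, index=cell_names, columns=comp),
        loadings=pd.DataFrame(V, index=genes, columns=comp),
        partial_inertias=inertias,
        ratio=ratio,
        table_of_cell=pd.Series(table_idx, index=cell_names),
    )


# ---------------------------------------------------------------------------
# consensus clustering (SC3-style) and agreement
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Per-cell binary cluster labels with a method tag."""

    labels: pd.Series
    method: str


def _spearman_distance(X: np.ndarray) -> np.ndarray:
    R = np.apply_along_axis(rankdata, 1, X)
    return 1.0 - np.corrcoef(R)


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    return 1.0 - np.corrcoef(X)


def _pca_embedding(D: np.ndarray, d_max: int) -> np.ndarray:
    Dc = D - D.mean(axis=0)
    U, s, _ = np.linalg.svd(Dc, full_matrices=False)
    return U[:, :d_max] * s[:d_max]


def _laplacian_embedding(D: np.ndarray, d_max: int) -> np.ndarray:
    A = np.exp(-D / max(D.max(), 1e-12))
    deg = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    L = np.eye(len(D)) - inv_sqrt[:, None] * A * inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(L)
    return vecs[:, :d_max]


def consensus_cluster(
    expr: ad.AnnData | np.ndarray,
    genes: list[str] | None = None,
    k: int = 2,
    seed: int = 0,
    max_cells: int = 1000,
    n_dims: int = 4,
    n_restarts: int = 10,
) -> ClusterAssignment:
    """SC3-style consensus clustering of cells in a candidate-gene space.

    Three cell-cell distances (Euclidean, Pearson, Spearman) are each
    transformed two ways (PCA of the distance matrix; eigenvectors of its
    normalized graph Laplacian), k-means with ``n_restarts`` restarts is run
    over ``n_dims`` leading-dimension counts spanning 4-7% of n, and the
    binary co-clustering matrices are averaged into a consensus matrix that
    is cut by complete-linkage hierarchical clustering at k. Beyond
    ``max_cells`` cells a random subsample is clustered and the remaining
    cells are assigned to the nearest consensus-cluster centroid in gene
    space. Deterministic given the seed.
    """
    if isinstance(expr, ad.AnnData):
        sub = expr[:, genes] if genes is not None else expr
        X = _dense(sub.X).astype(float)
        cells = list(sub.obs_names)
    else:
        X = np.asarray(expr, float)
        cells = [f"c{i}" for i in range(X.shape[0])]
    n = X.shape[0]
    if n < 2 * k:
        raise ValueError("need at least 2k cells")
    if float(X.std()) == 0:
        raise ValueError("constant expression matrix cannot be clustered")

    rng = np.random.default_rng(int(seed))
    if n > max_cells:
        idx = np.sort(rng.choice(n, size=max_cells, replace=False))
    else:
        idx = np.arange(n)
    S = X[idx]
    m = len(idx)

    d_lo = max(int(np.floor(0.04 * m)), 2)
    d_hi = max(int(np.floor(0.07 * m)), d_lo + 1)
    dims = sorted(set(np.linspace(d_lo, d_hi, n_dims).astype(int)))
    d_max = max(dims)

    distances = [
        squareform(pdist(S, metric="euclidean")),
        _pearson_distance(S),
        _spearman_distance(S),
    ]
    consensus = np.zeros((m, m))
    runs = 0
    for D in distances:
        np.nan_to_num(D, copy=False)
        for emb in (_pca_embedding(D, d_max), _laplacian_embedding(D, d_max)):
            for d in dims:
                km = KMeans(
                    n_clusters=k,
                    n_init=n_restarts,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
                lab = km.fit_predict(emb[:, :d])
                consensus += lab[:, None] == lab[None, :]
                runs += 1
    consensus /= runs
    Z = linkage(squareform(1.0 - consensus, checks=False), method="complete")
    sub_labels = fcluster(Z, k, criterion="maxclust") - 1

    if m < n:
        centroids = np.vstack([S[sub_labels == c].mean(axis=0) for c in range(k)])
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        labels[idx] = sub_labels
    else:
        labels = sub_labels
    return ClusterAssignment(
        labels=pd.Series(labels, index=cells, name="cluster"), method="consensus"
    )


def matthews_correlation(a, b) -> float:
    """Matthews correlation between two binary labelings, maximized over
    the two possible label matchings (cluster labels are arbitrary).

    Returns 0 with a warning for degenerate single-class input."""
    la = a.labels if isinstance(a, ClusterAssignment) else pd.Series(np.asarray(a))
    lb = b.labels if isinstance(b, ClusterAssignment) else pd.Series(np.asarray(b))
    xa = pd.factorize(np.asarray(la))[0]
    xb = pd.factorize(np.asarray(lb))[0]
    if len(xa) != len(xb):
        raise ValueError("labelings cover different cells")
    if len(np.unique(xa)) < 2 or len(np.unique(xb)) < 2:
        warnings.warn("degenerate single-class labeling; MCC undefined, returning 0")
        return 0.0
    tp = float(((xa == 1) & (xb == 1)).sum())
    tn = float(((xa == 0) & (xb == 0)).sum())
    fp = float(((xa == 0) & (xb == 1)).sum())
    fn = float(((xa == 1) & (xb == 0)).sum())
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    mcc = (tp * tn - fp * fn) / denom
    return float(abs(mcc))


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

@dataclass
class SignaturePipelineResult:
    """All artifacts of the signature-derivation pipeline."""

    candidates: list[str]
    expr_z: ad.AnnData
    pca: PCAResult
    gmm: GMMFit
    assignment: ClusterAssignment
    lineage_calls: pd.Series  # blood | microglia per cell
    signature: SignatureGeneSet


def derive_signature(
    counts_tam: ad.AnnData,
    mouse_table: pd.DataFrame,
    homology: pd.DataFrame,
    min_mean_cpm: float = 1.0,
    threshold: float = 0.2,
    n_components: int = 10,
    seed: int = 0,
) -> SignaturePipelineResult:
    """Run the full signature derivation on a TAM counts matrix.

    Steps: CPM, homologue feature selection, log2(CPM/10+1), per-platform
    z-score, Varimax PCA, two-component GMM partition of PC1, threshold
    extraction with enrichment-based lineage orientation. Per-cell lineage
    calls map each GMM component to the lineage of its PC1 side.
    """
    from .preprocess import cpm_normalize

    cpm = cpm_normalize(counts_tam)
    candidates = select_homologue_features(cpm, mouse_table, homology, min_mean_cpm)
    logx = log_transform(cpm)
    z = zscore_by_platform(logx)
    pca = pca_varimax(z, candidates, n_components=n_components)
    gmm = fit_gmm_1d(pca.pc1_scores.to_numpy(), seed=seed)
    signature = extract_signature(pca, mouse_table, homology, threshold=threshold)
    assignment = ClusterAssignment(
        labels=pd.Series(gmm.labels, index=pca.cells, name="cluster"),
        method="gmm-pc1",
    )
    # component 1 has the higher PC1 mean; on a blood-positive axis it is blood
    high_is_blood = signature.blood_sign > 0
    lineage_of_label = {0: MICROGLIA if high_is_blood else BLOOD,
                        1: BLOOD if high_is_blood else MICROGLIA}
    lineage_calls = assignment.labels.map(lineage_of_label)
    return SignaturePipelineResult(
        candidates=candidates,
        expr_z=z,
        pca=pca,
        gmm=gmm,
        assignment=assignment,
        lineage_calls=lineage_calls,
        signature=signature,
    )
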