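"""Differential expression between TAM lineages and marker co-occurrence.

The two-group test is a negative-binomial Wald test in the style of the
classic bulk RNA-seq estimators: library sizes are normalized with
median-of-ratios size factors, per-gene dispersions are estimated by the
method of moments and shrunk halfway (on the log scale) toward a fitted
mean-dispersion trend, and the group log-fold-change is tested against its
delta-method standard error. Co-occurrence of detection between gene pairs
is summarized by odds ratios (Haldane-Anscombe corrected when a cell of
the 2x2 table is empty) with two-sided Fisher exact p values, adjusted by
Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 table: the p value sums the
    hypergeometric probabilities of all tables (at the observed margins) no
    more probable than the observed one. Returns (odds ratio, p)."""
    orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orr), float(p)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (cells x genes counts).

    The reference is the geometric mean over cells; for sparse single-cell
    data the geometric mean is taken over the positive counts of each gene
    and the per-cell median is computed over that cell's detected genes.
    Falls back to total-count scaling if no gene is usable."""
    counts = np.asarray(counts, float)
    pos = counts > 0
    n_pos = pos.sum(axis=0)
    usable = n_pos >= max(2, counts.shape[0] // 2)
    if not usable.any():
        totals = counts.sum(axis=1)
        return totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    with np.errstate(divide="ignore"):
        logc = np.where(pos, np.log(np.maximum(counts, 1e-300)), 0.0)
    ref = np.exp(logc[:, usable].sum(axis=0) / np.maximum(n_pos[usable], 1))
    sf = np.empty(counts.shape[0])
    for i in range(counts.shape[0]):
        det = pos[i, usable]
        if det.any():
            sf[i] = np.median(counts[i, usable][det] / ref[det])
        else:
            sf[i] = np.nan
    if np.isnan(sf).any() or (sf <= 0).any():
        totals = counts.sum(axis=1)
        fallback = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
        bad = np.isnan(sf) | (sf <= 0)
        sf[bad] = fallback[bad]
    # normalize to geometric mean 1
    return sf / np.exp(np.mean(np.log(sf)))


def _dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by least squares on moderately expressed
    genes, clipped to non-negative coefficients."""
    ok = (mu > 1e-3) & np.isfinite(alpha) & (alpha > 0)
    if ok.sum() < 10:
        a0, a1 = max(np.nanmedian(alpha[ok]) if ok.any() else 0.1, 1e-4), 0.0
    else:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(A, alpha[ok], rcond=None)
        a0, a1 = max(coef[0], 1e-4), max(coef[1], 0.0)
    return a0 + a1 / np.maximum(mu, 1e-3)


def differential_expression(
    counts: ad.AnnData | pd.DataFrame,
    groups,
    min_cells_per_group: int = 5,
) -> pd.DataFrame:
    """Negative-binomial Wald test between two cell groups.

    Returns one row per gene (all-zero genes excluded) with the log2
    fold-change of the second group level over the first, the Wald
    statistic, p value and BH-adjusted p value.
    """
    if isinstance(counts, ad.AnnData):
        X = _dense(counts.X).astype(float)
        gene_names = np.asarray(counts.var_names)
        cell_index = counts.obs_names
    else:
        X = counts.to_numpy(float)
        gene_names = np.asarray(counts.columns)
        cell_index = counts.index
    g = pd.Series(np.asarray(groups), index=cell_index).astype(str)
    levels = sorted(pd.unique(g))  # deterministic contrast: second over first
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    m0 = (g == levels[0]).to_numpy()
    m1 = (g == levels[1]).to_numpy()
    if m0.sum() < min_cells_per_group or m1.sum() < min_cells_per_group:
        raise ValueError(f"each group needs >= {min_cells_per_group} cells")

    nonzero = X.sum(axis=0) > 0
    X = X[:, nonzero]
    gene_names = gene_names[nonzero]

    sf = size_factors(X)
    Y = X / sf[:, None]
    n0, n1 = int(m0.sum()), int(m1.sum())
    mean0 = Y[m0].mean(axis=0)
    mean1 = Y[m1].mean(axis=0)
    mu = Y.mean(axis=0)

    # pooled within-group variance of normalized counts
    v0 = Y[m0].var(axis=0, ddof=1)
    v1 = Y[m1].var(axis=0, ddof=1)
    var_w = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    shot = mu * np.mean(1.0 / sf)  # Poisson component after scaling
    alpha_raw = np.maximum((var_w - shot) / np.maximum(mu**2, 1e-12), 1e-8)
    alpha_trend = _dispersion_trend(mu, alpha_raw)
    alpha = np.exp(0.5 * np.log(alpha_raw) + 0.5 * np.log(np.maximum(alpha_trend, 1e-8)))

    # moderated group means to keep the contrast finite for sparse genes
    eps0 = 0.5 / n0
    eps1 = 0.5 / n1
    m0s, m1s = mean0 + eps0, mean1 + eps1
    beta = np.log(m1s) - np.log(m0s)
    inv_sf = np.mean(1.0 / sf)
    se2 = (inv_sf / m1s + alpha) / n1 + (inv_sf / m0s + alpha) / n0
    se = np.sqrt(se2)
    stat = beta / se
    df = n0 + n1 - 2
    p = 2.0 * stats.t.sf(np.abs(stat), df=df)
    padj = bh_adjust(p)

    out = pd.DataFrame(
        {
            "gene": gene_names,
            "log2_fold_change": beta / np.log(2.0),
            "base_mean": mu,
            "dispersion": alpha,
            "stat": stat,
            "p": p,
            "padj": padj,
        }
    ).set_index("gene", drop=False)
    out.index.name = None
    out.attrs["contrast"] = (str(levels[1]), str(levels[0]))
    return out


def coexpression_fraction(
    expr: ad.AnnData,
    gene_a: str,
    gene_b: str,
    detect_threshold: float = 0.0,
) -> float:
    """Fraction of cells detecting ``gene_a`` (CPM strictly above threshold)
    that also detect ``gene_b``. NaN with a warning if no cell expresses
    ``gene_a``."""
    if expr.uns.get("scale") != "cpm":
        raise ValueError("coexpression_fraction expects CPM-scale expression")
    for gene in (gene_a, gene_b):
        if gene not in expr.var_names:
            raise KeyError(f"gene {gene!r} not in matrix")
    xa = _dense(expr[:, gene_a].X).ravel() > detect_threshold
    xb = _dense(expr[:, gene_b].X).ravel() > detect_threshold
    if not xa.any():
        warnings.warn(f"no cell expresses {gene_a!r}; co-expression undefined")
        return float("nan")
    return float((xa & xb).sum() / xa.sum())


def cooccurrence_odds_ratios(
    expr: ad.AnnData,
    pairs: list[tuple[str, str]],
    detect_threshold: float = 0.0,
) -> pd.DataFrame:
    """Detection co-occurrence odds ratios for gene pairs.

    Detection is binarized at ``detect_threshold`` CPM; the odds ratio uses
    the Haldane-Anscombe +0.5 correction on every cell when any cell of the
    2x2 table is zero; the p value is the two-sided Fisher exact test on
    the uncorrected table; BH adjustment is across all reported pairs.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    if expr.uns.get("scale") != "cpm":
        raise ValueError("cooccurrence_odds_ratios expects CPM-scale expression")
    X = _dense(expr.X)
    names = {g: i for i, g in enumerate(expr.var_names)}
    rows = []
    for ga, gb in pairs:
        if ga not in names or gb not in names:
            warnings.warn(f"pair ({ga}, {gb}) skipped: gene missing from matrix")
            continue
        da = X[:, names[ga]] > detect_threshold
        db = X[:, names[gb]] > detect_threshold
        a = int((da & db).sum())
        b = int((da & ~db).sum())
        c = int((~da & db).sum())
        d = int((~da & ~db).sum())
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        _, p = fisher_exact_2x2(a, b, c, d)
        frac = float(a / (a + b)) if (a + b) > 0 else float("nan")
        rows.append(
            {
                "gene_a": ga, "gene_b": gb,
                "n_both": a, "n_a_only": b, "n_b_only": c, "n_neither": d,
                "odds_ratio": orr, "p": p, "cond_coexpression": frac,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out.p.to_numpy())
    return out
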