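"""Cell quality control, normalization, and TAM-vs-neoplastic classification.

Cells are quality-filtered on transcript diversity and depth, counts are
scaled to counts per million (CPM), and each cell is classified as a
tumor-associated macrophage (TAM), a neoplastic cell, or left unassigned.
Neoplastic evidence combines expressed clonal somatic mutations (alt-read
support at loci known to be clonal from exome calls) with copy-number
signal: the mean expression shift over called CNV segments relative to a
control cell population, which must also agree in direction with the
exome-level amp/del calls. Cells without neoplastic evidence are called
TAMs when they robustly express a panel of canonical macrophage markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

TAM = "TAM"
NEOPLASTIC_CLASS = "neoplastic"
UNASSIGNED = "unassigned"


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def cpm_normalize(adata: ad.AnnData) -> ad.AnnData:
    """Scale each cell's counts to counts per million.

    Cells with zero total counts cannot be normalized; they are excluded
    from the result with a warning rather than silently propagating NaNs.
    """
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"excluding {int(empty.sum())} all-zero cell(s) from CPM normalization: "
            f"{list(adata.obs_names[empty])}"
        )
        adata = adata[~empty].copy()
        X = X[~empty]
        totals = totals[~empty]
    cpm = X / totals[:, None] * 1e6
    out = ad.AnnData(X=cpm, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns["scale"] = "cpm"
    return out


def filter_cells(
    adata: ad.AnnData, min_genes: int = 800, min_reads: int = 50_000
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove low-quality cells by thresholding detected genes and depth.

    Both thresholds are inclusive (a cell at exactly the threshold is
    retained). Total counts stand in for uniquely aligned reads when no
    alignment metadata exists. Returns the filtered matrix and a QC record
    for every input cell.
    """
    if min_genes < 0 or min_reads < 0:
        raise ValueError("QC thresholds must be non-negative")
    X = _dense(adata.X)
    genes_detected = (X > 0).sum(axis=1)
    reads = X.sum(axis=1)
    passed = (genes_detected >= min_genes) & (reads >= min_reads)
    qc = pd.DataFrame(
        {
            "cell_id": list(adata.obs_names),
            "genes_detected": genes_detected.astype(int),
            "aligned_reads": reads.astype(int),
            "passed": passed,
        }
    )
    return adata[np.asarray(passed)].copy(), qc


def segment_gene_mask(var: pd.DataFrame, segment: pd.Series) -> np.ndarray:
    """Boolean mask of genes overlapping a CNV segment (0-based half-open)."""
    return (
        (var.chrom == segment.chrom)
        & (var.start < segment.end)
        & (var.end > segment.start)
    ).to_numpy()


def quantify_cnv_in_cells(
    expr: ad.AnnData,
    segments: pd.DataFrame,
    control_cells: set[str] | list[str],
    min_genes_per_segment: int = 5,
    sd_floor: float = 0.1,
) -> pd.DataFrame:
    """Per-cell, per-segment CNV scores referenced to a control population.

    For each segment the score of a cell is the mean, over the segment's
    genes, of the control-referenced z of log expression:
    ``(x - mean_control) / max(sd_control, sd_floor)``. Segments covering
    fewer than ``min_genes_per_segment`` measured genes are reported as NaN.
    ``expr`` must be on a log scale.
    """
    if expr.uns.get("scale") not in {"logcpm", "log"}:
        raise ValueError("quantify_cnv_in_cells expects log-scale expression")
    control_cells = set(control_cells)
    if not control_cells:
        raise ValueError("control_cells must be non-empty")
    ctrl_mask = np.array([c in control_cells for c in expr.obs_names])
    if not ctrl_mask.any():
        raise ValueError("no control cells present in the expression matrix")
    X = _dense(expr.X)
    ctrl = X[ctrl_mask]
    mu = ctrl.mean(axis=0)
    sd = np.maximum(ctrl.std(axis=0, ddof=1), sd_floor)

    scores = {}
    any_genes = False
    for i, (_, seg) in enumerate(segments.iterrows()):
        mask = segment_gene_mask(expr.var, seg)
        name = f"{seg.chrom}:{seg.start}-{seg.end}:{seg.direction}"
        if mask.sum() < min_genes_per_segment:
            scores[name] = np.full(X.shape[0], np.nan)
            continue
        any_genes = True
        z = (X[:, mask] - mu[mask]) / sd[mask]
        scores[name] = z.mean(axis=1)
    if len(segments) and not any_genes:
        raise ValueError("no CNV segment overlaps enough measured genes")
    out = pd.DataFrame(scores, index=list(expr.obs_names))
    out.attrs["directions"] = {
        f"{s.chrom}:{s.start}-{s.end}:{s.direction}": s.direction
        for _, s in segments.iterrows()
    }
    return out


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds for TAM-vs-neoplastic classification."""

    cnv_score: float = 0.5  # mean |segment score| above which CNV evidence counts
    cnv_concordance: float = 2.0 / 3.0  # fraction of segments matching call direction
    marker_score: float = 1.0  # mean marker log2(CPM/10+1) above which a cell is a TAM
    min_alt_reads: int = 2  # alt reads required to count an expressed SNV


def classify_cells(
    expr: ad.AnnData,
    markers: list[str],
    variants: pd.DataFrame,
    cnv_scores: pd.DataFrame | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> pd.DataFrame:
    """Classify each cell as TAM, neoplastic, or unassigned.

    A cell is neoplastic if it expresses at least one clonal SNV with
    sufficient alt-read support, or if its CNV evidence is strong (mean
    absolute segment score above threshold with direction concordance).
    A non-neoplastic cell is a TAM when its mean marker expression exceeds
    the marker threshold; otherwise it is unassigned. ``expr`` must be on
    the log2(CPM/10+1) scale. Evidence precedence: mutations and CNVs
    override marker expression.
    """
    if not markers:
        raise ValueError("marker set must be non-empty")
    present = [m for m in markers if m in expr.var_names]
    missing = sorted(set(markers) - set(present))
    if missing:
        warnings.warn(f"marker genes absent from matrix, skipped: {missing}")
    if not present:
        raise ValueError("none of the marker genes are present in the matrix")
    if expr.uns.get("scale") not in {"logcpm", "log"}:
        raise ValueError("classify_cells expects log-scale expression")

    X = _dense(expr[:, present].X)
    marker_score = pd.Series(X.mean(axis=1), index=list(expr.obs_names))

    supported = variants[variants.alt_count >= thresholds.min_alt_reads]
    n_snv = supported.groupby("cell_id").size()
    n_snv = n_snv.reindex(expr.obs_names, fill_value=0)

    if cnv_scores is not None and cnv_scores.shape[1] > 0:
        cs = cnv_scores.reindex(expr.obs_names)
        directions = cnv_scores.attrs.get("directions", {})
        sign = np.array([1.0 if directions.get(c, "amp") == "amp" else -1.0
                         for c in cs.columns])
        vals = cs.to_numpy()
        valid = ~np.isnan(vals)
        n_valid = valid.sum(axis=1)
        denom = np.maximum(n_valid, 1)
        mean_abs = np.where(n_valid > 0, np.nansum(np.abs(vals), axis=1) / denom, 0.0)
        match = ((np.sign(vals) == sign[None, :]) & valid).sum(axis=1)
        concord = np.where(n_valid > 0, match / denom, 0.0)
    else:
        mean_abs = np.zeros(expr.n_obs)
        concord = np.zeros(expr.n_obs)

    cnv_evidence = (mean_abs > thresholds.cnv_score) & (concord >= thresholds.cnv_concordance)
    neoplastic = (n_snv.to_numpy() >= 1) | cnv_evidence
    tam = ~neoplastic & (marker_score.to_numpy() > thresholds.marker_score)
    cls = np.where(neoplastic, NEOPLASTIC_CLASS, np.where(tam, TAM, UNASSIGNED))

    return pd.DataFrame(
        {
            "cell_id": list(expr.obs_names),
            "cell_class": cls,
            "marker_score": marker_score.to_numpy(),
            "n_snv": n_snv.to_numpy(),
            "cnv_mean_abs": mean_abs,
            "cnv_concordance": concord,
        }
    ).set_index("cell_id", drop=False)


@dataclass
class PreprocessResult:
    """Output bundle of the preprocessing stage."""

    counts: ad.AnnData  # QC-passed raw counts
    qc: pd.DataFrame
    log_expr: ad.AnnData  # log2(CPM/10+1)
    cnv_scores: pd.DataFrame
    annotation: pd.DataFrame

    @property
    def tam_cells(self) -> list[str]:
        return list(self.annotation.index[self.annotation.cell_class == TAM])


def run_preprocess(
    counts: ad.AnnData,
    segments: pd.DataFrame,
    variants: pd.DataFrame,
    markers: list[str] = None,
    min_genes: int = 800,
    min_reads: int = 50_000,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> PreprocessResult:
    """QC, normalize and classify a raw single-cell counts matrix.

    Control cells for CNV quantification are chosen provisionally as cells
    with robust marker expression and no expressed clonal SNV (the in-silico
    analog of a non-malignant control sample); classification is then run
    with the resulting CNV scores.
    """
    from .signature import log_transform  # local import avoids cycle at module load

    if markers is None:
        markers = [m for m in
                   ("PTPRC", "ITGAM", "AIF1", "CD14", "CSF1R", "HLA-DRA")
                   if m in counts.var_names]
    filtered, qc = filter_cells(counts, min_genes=min_genes, min_reads=min_reads)
    log_expr = log_transform(cpm_normalize(filtered))

    provisional = classify_cells(log_expr, markers, variants, cnv_scores=None,
                                 thresholds=thresholds)
    control = list(provisional.index[provisional.cell_class == TAM])
    if len(segments) and control:
        cnv_scores = quantify_cnv_in_cells(log_expr, segments, control)
    else:
        cnv_scores = pd.DataFrame(index=list(log_expr.obs_names))
    annotation = classify_cells(log_expr, markers, variants, cnv_scores,
                                thresholds=thresholds)
    return PreprocessResult(
        counts=filtered, qc=qc, log_expr=log_expr,
        cnv_scores=cnv_scores, annotation=annotation,
    )
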