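"""Readers and writers for the pipeline's on-disk formats.

Single-cell counts travel as Matrix Market MTX (genes x cells) with
``genes.tsv`` (gene_id, symbol, chrom, start, end; 0-based half-open
coordinates) and ``cells.tsv`` (cell_id, sample_id, platform) sidecars.
Everything else is plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

GENE_COLS = ["gene_id", "symbol", "chrom", "start", "end"]
CELL_COLS = ["cell_id", "sample_id", "platform"]


def write_counts(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write a counts AnnData as matrix.mtx + genes.tsv + cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(outdir / "matrix.mtx", X.T.astype(int))  # genes x cells
    adata.var[GENE_COLS].to_csv(outdir / "genes.tsv", sep="\t", index=False)
    adata.obs[CELL_COLS].to_csv(outdir / "cells.tsv", sep="\t", index=False)
    return outdir


def read_counts(indir: str | Path) -> ad.AnnData:
    """Read a counts directory written by :func:`write_counts`."""
    indir = Path(indir)
    M = scipy.io.mmread(indir / "matrix.mtx").tocsr().T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    genes.index = pd.Index(genes.symbol.astype(str))
    genes.index.name = None
    cells.index = pd.Index(cells.cell_id.astype(str))
    cells.index.name = None
    adata = ad.AnnData(X=M.astype(np.int32), obs=cells, var=genes)
    adata.uns["scale"] = "counts"
    return adata


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix(df: pd.DataFrame, path: str | Path) -> Path:
    """Sample-by-gene matrix TSV with sample ids in the first column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True, index_label="sample_id")
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index.name = None
    return df


def write_study(study, outdir: str | Path) -> Path:
    """Write every input file of a simulated study plus its truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(study.counts, outdir / "counts")
    write_table(study.cnv_segments, outdir / "cnv_segments.tsv")
    write_table(study.variants, outdir / "variants.tsv")
    write_table(study.mouse_table, outdir / "mouse_lineage_table.tsv")
    write_table(study.homology, outdir / "homology_map.tsv")
    truth_lineage = study.truth.cell_lineage.rename("true_lineage").reset_index()
    truth_lineage.columns = ["cell_id", "true_lineage"]
    write_table(truth_lineage, outdir / "truth_cell_lineage.tsv")
    write_table(study.truth.true_signature, outdir / "truth_signature.tsv")
    return outdir


def read_mouse_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    df["dual_model"] = df.dual_model.astype(bool)
    return df
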