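"""Mapping the lineage signature onto regional expression atlases.

Each microdissected sample is scored by the mean z-scored expression of the
blood-derived and microglial signature genes; per-structure summaries and a
one-vs-rest rank-sum enrichment test (BH-adjusted across structure-lineage
combinations) identify anatomic compartments enriched for either lineage.
Samples from one tumor are not independent; the test treats them as such,
which is recorded as a caveat in the output.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .compare import bh_adjust
from .simulate import BLOOD, MICROGLIA, RegionalAtlas


def regional_signature_scores(
    atlas: RegionalAtlas | pd.DataFrame,
    signature,
    structures: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample lineage scores and per-structure summaries.

    Returns ``(sample_scores, structure_summary)``: the former has one row
    per sample with ``blood``/``microglia`` mean-z scores and the structure
    label; the latter aggregates mean and SD per structure.
    """
    if isinstance(atlas, RegionalAtlas):
        expr = atlas.expr
        structures = atlas.structures
    else:
        expr = atlas
        if structures is None:
            raise ValueError("structure labels required with a plain matrix")
    entries = signature.as_frame() if hasattr(signature, "as_frame") else signature
    scores = {}
    for lineage in (BLOOD, MICROGLIA):
        genes = [g for g in entries.gene[entries.lineage == lineage] if g in expr.columns]
        if not genes:
            raise ValueError(f"no {lineage} signature gene overlaps the atlas")
        scores[lineage] = expr[genes].mean(axis=1)
    out = pd.DataFrame(scores)
    out["structure"] = pd.Series(structures, index=out.index)
    summary = (
        out.groupby("structure")[[BLOOD, MICROGLIA]]
        .agg(["mean", "std", "count"])
        .sort_index()
    )
    return out, summary


def structure_enrichment(
    sample_scores: pd.DataFrame,
    structures: pd.Series | None = None,
) -> pd.DataFrame:
    """One-vs-rest rank-sum enrichment of lineage scores per structure.

    For every structure and lineage, a two-sided Mann-Whitney test compares
    that structure's samples with all others; BH adjustment spans all
    structure-lineage tests. Effect size is the difference of mean scores.
    Structures with a single sample are skipped with a warning.
    """
    labels = sample_scores["structure"] if structures is None else pd.Series(
        np.asarray(structures), index=sample_scores.index
    )
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("need at least two structures for enrichment")
    rows = []
    for structure in levels:
        mask = (labels == structure).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"structure {structure!r} has < 2 samples; skipped")
            continue
        for lineage in (BLOOD, MICROGLIA):
            x = sample_scores.loc[mask, lineage].to_numpy()
            y = sample_scores.loc[~mask, lineage].to_numpy()
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append(
                {
                    "structure": structure,
                    "lineage": lineage,
                    "n_in": int(mask.sum()),
                    "effect_size": float(x.mean() - y.mean()),
                    "u_stat": float(stat),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out.p.to_numpy())
    out.attrs["caveat"] = (
        "samples sharing a tumor are treated as independent by this test"
    )
    return out
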