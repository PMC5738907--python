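"""Synthetic data generators for the TAM-ontogeny pipeline.

Every input the pipeline consumes can be generated here with known ground
truth: a dual-platform single-cell cohort of tumor-associated macrophages
(TAMs) and neoplastic cells, the murine lineage differential-expression
table and mouse-to-human homology map used for feature selection, clonal
SNV/CNV evidence for neoplastic-cell classification, bulk cohorts with
proportional-hazards survival, and a regional expression atlas with
structure-specific lineage enrichment.

The counts model is a negative binomial with a per-platform log-normal
library size and per-platform Bernoulli detection thinning — the minimal
model that reproduces the depth/detection differences between a full-length
microfluidic platform ("C1") and a plate-based full-length platform
("SmartSeq2"). All generators are pure functions of their arguments,
including the seed: the same seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

BLOOD = "blood"
MICROGLIA = "microglia"
NEOPLASTIC = "neoplastic"

#: Default anatomic structures of the regional atlas, ordered roughly from
#: the infiltrating margin to the tumor core.
DEFAULT_STRUCTURES: tuple[str, ...] = (
    "leading_edge",
    "infiltrated_white_matter",
    "cellular_tumor",
    "hyperplastic_blood_vessels",
    "microvascular_proliferation",
    "perinecrotic_zone",
)

#: Default per-structure lineage bias (z-units). Positive values shift
#: blood-derived signature genes up, negative values shift microglial
#: signature genes up, mirroring the enrichment of blood-derived TAMs in
#: vascular and necrotic compartments and of microglia at the invasive edge.
DEFAULT_STRUCTURE_BIAS: dict[str, float] = {
    "leading_edge": -1.5,
    "infiltrated_white_matter": -1.0,
    "cellular_tumor": 0.0,
    "hyperplastic_blood_vessels": 1.5,
    "microvascular_proliferation": 1.5,
    "perinecrotic_zone": 1.0,
}

DEFAULT_MARKERS: tuple[str, ...] = (
    "PTPRC",
    "ITGAM",
    "AIF1",
    "CD14",
    "CSF1R",
    "HLA-DRA",
)

# Fixed spawn keys for stage-specific child generators (one master seed,
# child streams derived by fixed offsets).
_STAGE = {
    "genes": 1,
    "cells": 2,
    "counts": 3,
    "variants": 4,
    "mouse": 5,
    "homology": 6,
    "bulk": 7,
    "regional": 8,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named pipeline stage under one master seed."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STAGE[stage],)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic single-cell cohort.

    Defaults emulate a realistic clinical study design: 19 patients, roughly
    3000 TAMs after QC of which ~70% are blood-derived, a homologue-filtered
    candidate pool of 237 genes containing 66 truly lineage-specific genes,
    and two capture platforms with distinct depth/detection characteristics.
    """

    n_samples: int = 19
    n_cells_per_sample: int = 200
    n_genes: int = 2000
    n_candidate_genes: int = 237
    n_true_signature: int = 66
    bmdm_fraction: float = 0.70
    neoplastic_fraction: float = 0.20
    #: mean |log2 fold-change| between lineages for true signature genes;
    #: core lineage markers are near on/off between ontogenies, so the
    #: default is a strong (8-fold) contrast
    effect_size: float = 3.0
    #: fraction of samples captured on the "C1" platform
    platform_mix: float = 0.5
    detection_rates: Mapping[str, float] = field(
        default_factory=lambda: {"C1": 0.75, "SmartSeq2": 0.55}
    )
    #: (mean, sigma) of log library size per platform
    library_size_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "C1": (math.log(3.0e5), 0.35),
            "SmartSeq2": (math.log(2.0e5), 0.35),
        }
    )
    nb_dispersion: float = 0.3
    n_cnv_segments: int = 4
    cnv_segment_genes: int = 30
    cnv_fold: float = 2.0
    n_variants: int = 25
    snv_capture_rate: float = 0.5
    #: fraction of cells with degraded libraries, planted to exercise QC
    lowq_fraction: float = 0.03
    marker_genes: tuple[str, ...] = DEFAULT_MARKERS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_cells_per_sample", "n_genes",
                     "n_candidate_genes", "n_true_signature", "n_cnv_segments",
                     "n_variants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("bmdm_fraction", "neoplastic_fraction", "platform_mix",
                     "snv_capture_rate", "lowq_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not (self.n_true_signature <= self.n_candidate_genes <= self.n_genes):
            raise ValueError(
                "need n_true_signature <= n_candidate_genes <= n_genes"
            )
        if self.cnv_fold <= 0 or self.nb_dispersion <= 0:
            raise ValueError("cnv_fold and nb_dispersion must be positive")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthLabels:
    """Ground truth attached to a simulated cohort; consumed only by tests
    and scoring code, never by the pipeline itself."""

    cell_lineage: pd.Series  # per cell: blood | microglia | neoplastic
    true_signature: pd.DataFrame  # columns: gene, lineage
    true_hr: float | None = None
    structure_enrichment: dict[str, float] | None = None

    @property
    def neoplastic(self) -> pd.Series:
        return self.cell_lineage == NEOPLASTIC


@dataclass
class StudyData:
    """A complete simulated single-cell study: everything the upstream half
    of the pipeline consumes, plus ground truth."""

    counts: ad.AnnData
    cnv_segments: pd.DataFrame  # chrom, start, end, direction
    variants: pd.DataFrame  # variant_id, cell_id, ref_count, alt_count
    mouse_table: pd.DataFrame
    homology: pd.DataFrame  # mouse_gene, human_gene
    truth: TruthLabels
    config: SimulationConfig


@dataclass
class BulkCohort:
    """Bulk expression cohort with survival annotations (log2(CPM+1) scale)."""

    expr: pd.DataFrame  # samples x genes
    clinical: pd.DataFrame  # time, event, age, gender, subtype
    truth_blood_content: pd.Series | None = None
    truth_high_group: pd.Series | None = None
    true_hr: float | None = None


@dataclass
class RegionalAtlas:
    """Regional expression matrix (z-scores per gene) with anatomic labels."""

    expr: pd.DataFrame  # samples x genes
    structures: pd.Series  # per sample
    tumors: pd.Series  # per sample
    truth_bias: dict[str, float]


# ---------------------------------------------------------------------------
# murine lineage table and homology map
# ---------------------------------------------------------------------------

def _build_mouse_table(
    genes: Sequence[str],
    lineages: Sequence[str],
    flagged: np.ndarray,
    effect_size: float,
    rng: np.random.Generator,
    padj_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Two-model murine differential-expression table with a planted set of
    dual-model lineage genes. Non-flagged genes fail the dual-model rule
    either by significance in only one model or by inconsistent sign."""
    n = len(genes)
    sign = np.where(np.asarray(lineages) == BLOOD, 1.0, -1.0)
    mag1 = np.abs(rng.normal(effect_size, 0.5, n)) + 0.25
    mag2 = np.abs(rng.normal(effect_size, 0.5, n)) + 0.25
    lfc1 = sign * mag1
    lfc2 = sign * mag2
    padj1 = rng.uniform(1e-8, padj_cutoff * 0.5, n)
    padj2 = rng.uniform(1e-8, padj_cutoff * 0.5, n)

    not_flagged = np.where(~flagged)[0]
    # half lose significance in model 2, half flip sign in model 2
    half = len(not_flagged) // 2
    lose = not_flagged[:half]
    flip = not_flagged[half:]
    padj2[lose] = rng.uniform(padj_cutoff * 2, 1.0, len(lose))
    lfc1[lose] = rng.normal(0.0, 0.4, len(lose))
    lfc2[lose] = rng.normal(0.0, 0.4, len(lose))
    lfc2[flip] = -lfc2[flip]

    table = pd.DataFrame(
        {
            "mouse_gene": list(genes),
            "lineage": list(lineages),
            "log2fc_model1": lfc1,
            "log2fc_model2": lfc2,
            "padj_model1": padj1,
            "padj_model2": padj2,
        }
    )
    table["dual_model"] = (
        (table.padj_model1 < padj_cutoff)
        & (table.padj_model2 < padj_cutoff)
        & (np.sign(table.log2fc_model1) == np.sign(table.log2fc_model2))
    )
    assert (table.dual_model.to_numpy() == flagged).all()
    table.attrs["padj_cutoff"] = padj_cutoff
    return table


def simulate_mouse_lineage_table(
    n_total: int, n_lineage: int, effect_size: float, seed: int
) -> pd.DataFrame:
    """Simulate the murine BMDM-vs-microglia differential-expression table.

    Exactly ``n_lineage`` genes are differential in both simulated models
    with a consistent sign (``dual_model`` flag); lineage signs among them
    are balanced. Remaining genes fail one of the dual-model conditions.
    """
    if n_total < 0 or n_lineage < 0:
        raise ValueError("counts must be non-negative")
    if n_lineage > n_total:
        raise ValueError("n_lineage must not exceed n_total")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STAGE["mouse"],)))
    genes = [f"mmGene{i + 1:05d}" for i in range(n_total)]
    # exact balance between lineages for the flagged set
    lineages = np.array([BLOOD if i % 2 == 0 else MICROGLIA for i in range(n_total)])
    flagged = np.zeros(n_total, dtype=bool)
    flagged[:n_lineage] = True
    return _build_mouse_table(genes, lineages, flagged, effect_size, rng)


def simulate_homology_map(
    mouse_genes: Sequence[str],
    drop_fraction: float,
    seed: int,
    human_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One-to-one mouse-to-human homology map covering
    ``floor(n * (1 - drop_fraction))`` of the input genes.

    If ``human_genes`` is not given, human symbols are derived by upper-casing
    the mouse symbol (the usual orthography convention between species).
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    mouse_genes = list(mouse_genes)
    n_keep = math.floor(len(mouse_genes) * (1.0 - drop_fraction))
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STAGE["homology"],)))
    keep_idx = np.sort(rng.choice(len(mouse_genes), size=n_keep, replace=False))
    kept = [mouse_genes[i] for i in keep_idx]
    if human_genes is None:
        human = [g.upper() for g in kept]
    else:
        human = [human_genes[i] for i in keep_idx]
    return pd.DataFrame({"mouse_gene": kept, "human_gene": human})


# ---------------------------------------------------------------------------
# single-cell cohort
# ---------------------------------------------------------------------------

def _gene_annotations(config: SimulationConfig, rng: np.random.Generator):
    """Gene universe: symbols, synthetic genome coordinates (1 Mb-spaced
    loci, 250 genes per chromosome) and baseline relative expression
    weights. Marker genes come first, then the candidate pool, then the
    homologue-filter decoys (suppressed expression), then background."""
    n = config.n_genes
    markers = list(config.marker_genes)
    n_mark = len(markers)
    symbols = markers + [f"G{i + 1:05d}" for i in range(n - n_mark)]
    per_chrom = 250
    chrom = np.array([f"chr{i // per_chrom + 1}" for i in range(n)])
    pos_in_chrom = np.arange(n) % per_chrom
    start = pos_in_chrom * 1_000_000
    end = start + 10_000
    genes = pd.DataFrame(
        {
            "gene_id": [f"ENSG{i + 1:07d}" for i in range(n)],
            "symbol": symbols,
            "chrom": chrom,
            "start": start,
            "end": end,
        }
    ).set_index("symbol", drop=False)
    genes.index.name = None

    weights = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    cand_lo = n_mark
    cand_hi = n_mark + config.n_candidate_genes
    # candidate genes are guaranteed expressed (mean CPM > 1 downstream)
    weights[cand_lo:cand_hi] = rng.lognormal(mean=0.8, sigma=0.7, size=config.n_candidate_genes)
    # homologue-map decoys: mapped lineage genes whose human counterpart is
    # not expressed in TAMs, exercising the mean-CPM filter
    n_decoy = 33
    decoy_lo, decoy_hi = cand_hi, cand_hi + n_decoy
    weights[decoy_lo:decoy_hi] = 1e-3
    weights[:n_mark] = math.e ** 0.5  # marker baseline; lineage-shifts applied per class
    genes["weight"] = weights
    return genes, (cand_lo, cand_hi), (decoy_lo, decoy_hi)


def _cell_annotations(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_cells = config.n_samples * config.n_cells_per_sample
    n_c1 = int(round(config.n_samples * config.platform_mix))
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    platforms = {s: ("C1" if i < n_c1 else "SmartSeq2") for i, s in enumerate(sample_ids)}
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i + 1:05d}" for i in range(n_cells)],
            "sample_id": np.repeat(sample_ids, config.n_cells_per_sample),
        }
    )
    cells["platform"] = cells.sample_id.map(platforms)
    is_neo = rng.random(n_cells) < config.neoplastic_fraction
    is_blood = rng.random(n_cells) < config.bmdm_fraction
    lineage = np.where(is_neo, NEOPLASTIC, np.where(is_blood, BLOOD, MICROGLIA))
    cells["true_lineage"] = lineage
    cells["lowq"] = rng.random(n_cells) < config.lowq_fraction
    return cells.set_index("cell_id", drop=False)


def _plant_segments(genes: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Contiguous CNV segments in the synthetic gene order, placed on
    chromosomes that hold no marker/candidate genes (chr3 onward)."""
    seg_len = config.cnv_segment_genes
    n = config.n_genes
    first_free = 2 * 250  # candidates and markers live on chr1-chr2
    usable = n - first_free
    segs = []
    if config.n_cnv_segments > 0:
        if usable < seg_len * config.n_cnv_segments:
            raise ValueError("not enough background genes to place CNV segments")
        block = usable // config.n_cnv_segments
        for k in range(config.n_cnv_segments):
            lo = first_free + k * block + int(rng.integers(0, max(block - seg_len, 1)))
            hi = lo + seg_len
            sub = genes.iloc[lo:hi]
            if sub.chrom.nunique() > 1:  # keep segments within one chromosome
                sub = sub[sub.chrom == sub.chrom.iloc[0]]
                hi = lo + len(sub)
            segs.append(
                {
                    "chrom": sub.chrom.iloc[0],
                    "start": int(sub.start.min()),
                    "end": int(sub.end.max()),
                    "direction": "amp" if k % 2 == 0 else "del",
                    "gene_lo": lo,
                    "gene_hi": hi,
                }
            )
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "direction", "gene_lo", "gene_hi"])


def simulate_single_cell_cohort(
    config: SimulationConfig,
) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame, TruthLabels]:
    """Simulate a dual-platform single-cell cohort of TAMs and neoplastic
    cells with planted lineage structure, CNVs and expressed clonal SNVs.

    Returns ``(counts, cnv_segments, variants, truth)``. ``counts`` is an
    AnnData of raw integer counts (cells x genes) with per-cell sample and
    platform labels and per-gene synthetic genome coordinates.
    """
    rng_g = _rng(config.seed, "genes")
    rng_c = _rng(config.seed, "cells")
    rng_x = _rng(config.seed, "counts")
    rng_v = _rng(config.seed, "variants")

    genes, (cand_lo, cand_hi), (decoy_lo, decoy_hi) = _gene_annotations(config, rng_g)
    cells = _cell_annotations(config, rng_c)
    segments = _plant_segments(genes, config, rng_g)

    n_genes = config.n_genes
    n_cells = len(cells)
    n_mark = len(config.marker_genes)

    # --- planted lineage signature -------------------------------------
    cand_idx = np.arange(cand_lo, cand_hi)
    sig_idx = cand_idx[: config.n_true_signature]
    sig_lineage = np.array(
        [BLOOD if i % 2 == 0 else MICROGLIA for i in range(config.n_true_signature)]
    )
    truth_sig = pd.DataFrame(
        {"gene": genes.symbol.to_numpy()[sig_idx], "lineage": sig_lineage}
    )

    # per-gene log2 shift applied in blood cells (microglia get the negative)
    half = config.effect_size / 2.0
    blood_shift = np.zeros(n_genes)
    blood_shift[sig_idx] = np.where(sig_lineage == BLOOD, half, -half)

    # neoplastic program: background genes upregulated in neoplastic cells
    neo_idx = rng_g.choice(
        np.arange(decoy_hi, n_genes), size=min(120, n_genes - decoy_hi), replace=False
    )
    neo_shift = np.zeros(n_genes)
    neo_shift[neo_idx] = 2.5
    # markers: high in TAMs, suppressed in neoplastic cells
    marker_tam, marker_neo = 4.0, -6.0

    log2w = np.log2(genes.weight.to_numpy())
    lineage = cells.true_lineage.to_numpy()
    shift = np.zeros((n_cells, n_genes))
    shift[lineage == BLOOD] += blood_shift
    shift[lineage == MICROGLIA] -= blood_shift
    shift[lineage == NEOPLASTIC] += neo_shift
    shift[:, :n_mark] += np.where(lineage == NEOPLASTIC, marker_neo, marker_tam)[:, None]

    # CNV scaling of neoplastic cells over planted segments
    log2_fold = math.log2(config.cnv_fold)
    for _, seg in segments.iterrows():
        sl = slice(int(seg.gene_lo), int(seg.gene_hi))
        delta = log2_fold if seg.direction == "amp" else -log2_fold
        shift[lineage == NEOPLASTIC, sl] += delta

    rel = np.exp2(log2w[None, :] + shift)
    props = rel / rel.sum(axis=1, keepdims=True)

    # --- library sizes and NB sampling ---------------------------------
    platforms = cells.platform.to_numpy()
    lib = np.empty(n_cells)
    det = np.empty(n_cells)
    for plat, (mu, sigma) in config.library_size_params.items():
        m = platforms == plat
        lib[m] = rng_x.lognormal(mean=mu, sigma=sigma, size=m.sum())
        det[m] = config.detection_rates[plat]
    lib[cells.lowq.to_numpy()] *= 0.04

    mu = props * lib[:, None]
    alpha = config.nb_dispersion
    nb_n = 1.0 / alpha
    nb_p = 1.0 / (1.0 + alpha * mu)
    counts = rng_x.negative_binomial(nb_n, nb_p)
    # Bernoulli detection thinning: the platform rate is the detection floor
    # for weakly expressed genes; detection saturates toward 1 with
    # expression, as in real capture chemistry
    p_det = 1.0 - (1.0 - det[:, None]) * np.exp(-mu / 20.0)
    detected = rng_x.random((n_cells, n_genes)) < p_det
    counts = counts * detected

    X = sp.csr_matrix(counts.astype(np.int32))
    adata = ad.AnnData(
        X=X,
        obs=cells[["cell_id", "sample_id", "platform"]].copy(),
        var=genes[["gene_id", "symbol", "chrom", "start", "end"]].copy(),
    )
    adata.uns["scale"] = "counts"

    # --- expressed clonal SNVs ------------------------------------------
    variants = _simulate_variants(config, genes, cells, neo_idx, rng_v)
    truth = TruthLabels(
        cell_lineage=cells.true_lineage.copy(), true_signature=truth_sig
    )
    seg_out = segments[["chrom", "start", "end", "direction"]].copy()
    return adata, seg_out, variants, truth


def _simulate_variants(
    config: SimulationConfig,
    genes: pd.DataFrame,
    cells: pd.DataFrame,
    neo_program_idx: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Allele-count table for clonal somatic SNVs hosted in expressed genes.

    Neoplastic cells carry alt-supporting reads at each locus with
    probability ``snv_capture_rate``; TAM cells show sparse reference-only
    coverage plus a rare single-read artifact (alt_count == 1)."""
    n_var = config.n_variants
    host = rng.choice(neo_program_idx, size=min(n_var, len(neo_program_idx)), replace=False)
    var_ids = [f"v{i + 1:03d}" for i in range(len(host))]
    rows: dict[str, list] = {"variant_id": [], "cell_id": [], "ref_count": [], "alt_count": []}
    is_neo = (cells.true_lineage == NEOPLASTIC).to_numpy()
    cell_ids = cells.cell_id.to_numpy()

    for vi, _g in zip(var_ids, host):
        captured = is_neo & (rng.random(len(cells)) < config.snv_capture_rate)
        alt = np.zeros(len(cells), dtype=int)
        ref = np.zeros(len(cells), dtype=int)
        alt[captured] = 2 + rng.poisson(2.0, captured.sum())
        ref[captured] = rng.poisson(2.0, captured.sum())
        # TAMs: occasional reference-only coverage, rare 1-read artifact
        tam_cov = ~is_neo & (rng.random(len(cells)) < 0.05)
        ref[tam_cov] = 1 + rng.poisson(2.0, tam_cov.sum())
        artifact = ~is_neo & (rng.random(len(cells)) < 0.005)
        alt[artifact] = 1
        keep = (alt + ref) > 0
        rows["variant_id"].extend([vi] * keep.sum())
        rows["cell_id"].extend(cell_ids[keep])
        rows["ref_count"].extend(ref[keep])
        rows["alt_count"].extend(alt[keep])
    return pd.DataFrame(rows)


def simulate_study(config: SimulationConfig | None = None) -> StudyData:
    """Simulate the full upstream study: single-cell cohort plus the murine
    lineage table and homology map wired so that the homologue filter
    recovers exactly the candidate pool.

    The murine table holds 836 genes; 300 are dual-model lineage genes, of
    which 270 have human homologues, of which ``n_candidate_genes`` map to
    genes expressed in the simulated TAMs (the rest map to silent decoys).
    The ``n_true_signature`` planted human genes carry matching murine
    lineage labels; the remaining candidates are lineage-specific in mouse
    only, with balanced random labels.
    """
    config = config or SimulationConfig()
    adata, segments, variants, truth = simulate_single_cell_cohort(config)
    rng_m = _rng(config.seed, "mouse")

    n_mark = len(config.marker_genes)
    cand_syms = adata.var.symbol.to_numpy()[n_mark : n_mark + config.n_candidate_genes]
    decoy_syms = adata.var.symbol.to_numpy()[
        n_mark + config.n_candidate_genes : n_mark + config.n_candidate_genes + 33
    ]

    n_total, n_flagged = 836, min(300, config.n_candidate_genes + 63)
    mouse_genes = [f"mmGene{i + 1:05d}" for i in range(n_total)]

    # murine lineage labels: match the planted human lineage for the true
    # signature genes, balanced pseudo-random labels elsewhere
    lineages = np.array([BLOOD if i % 2 == 0 else MICROGLIA for i in range(n_total)])
    true_map = dict(zip(truth.true_signature.gene, truth.true_signature.lineage))
    human_targets: list[str | None] = [None] * n_total
    n_cand = len(cand_syms)
    for i, sym in enumerate(cand_syms):
        human_targets[i] = sym
        if sym in true_map:
            lineages[i] = true_map[sym]
    for j, sym in enumerate(decoy_syms[: max(n_flagged - n_cand, 0)]):
        human_targets[n_cand + j] = sym

    flagged = np.zeros(n_total, dtype=bool)
    flagged[:n_flagged] = True
    mouse_table = _build_mouse_table(mouse_genes, lineages, flagged, config.effect_size, rng_m)

    # homology map: all flagged genes with a target, minus a dropped tail,
    # plus a slab of unflagged genes mapped to arbitrary symbols
    rng_h = _rng(config.seed, "homology")
    pairs: list[tuple[str, str]] = []
    with_target = [i for i in range(n_flagged) if human_targets[i] is not None]
    n_drop = 30
    kept_flagged = with_target[: max(len(with_target) - n_drop, 0)] if n_drop else with_target
    # never drop true-signature or candidate mappings needed downstream:
    kept_flagged = sorted(set(range(n_cand)) | set(kept_flagged))
    for i in kept_flagged:
        pairs.append((mouse_genes[i], human_targets[i]))
    unflagged = np.arange(n_flagged, n_total)
    extra = rng_h.choice(unflagged, size=min(300, len(unflagged)), replace=False)
    for i in np.sort(extra):
        pairs.append((mouse_genes[i], f"HS{i + 1:05d}"))
    homology = pd.DataFrame(pairs, columns=["mouse_gene", "human_gene"])

    return StudyData(
        counts=adata,
        cnv_segments=segments,
        variants=variants,
        mouse_table=mouse_table,
        homology=homology,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# two-group counts (differential-expression benchmarks)
# ---------------------------------------------------------------------------

def simulate_two_group_counts(
    n_cells_per_group: int = 100,
    n_genes: int = 1000,
    n_de: int = 0,
    log2_fold: float = 2.0,
    dispersion: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Negative-binomial counts for two cell groups with ``n_de`` planted
    differential genes at ``log2_fold`` (balanced up/down). Returns
    ``(counts cells x genes, group labels, boolean DE mask)``."""
    if n_de > n_genes:
        raise ValueError("n_de must not exceed n_genes")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STAGE["counts"],)))
    base = rng.lognormal(mean=2.5, sigma=1.0, size=n_genes)
    de_mask = np.zeros(n_genes, dtype=bool)
    de_mask[:n_de] = True
    sign = np.where(np.arange(n_genes) % 2 == 0, 1.0, -1.0)
    lfc = np.where(de_mask, sign * log2_fold, 0.0)

    n = n_cells_per_group
    lib = rng.lognormal(mean=0.0, sigma=0.3, size=2 * n)
    mu = np.empty((2 * n, n_genes))
    mu[:n] = base * np.exp2(-lfc / 2.0)
    mu[n:] = base * np.exp2(lfc / 2.0)
    mu *= lib[:, None]
    counts = rng.negative_binomial(1.0 / dispersion, 1.0 / (1.0 + dispersion * mu))
    cells = [f"c{i + 1:04d}" for i in range(2 * n)]
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    df = pd.DataFrame(counts, index=cells, columns=genes)
    groups = pd.Series(["A"] * n + ["B"] * n, index=cells, name="group")
    return df, groups, de_mask


# ---------------------------------------------------------------------------
# bulk cohort with survival
# ---------------------------------------------------------------------------

def simulate_bulk_cohort(
    n_samples: int,
    signature: pd.DataFrame,
    true_hr: float = 3.44,
    censor_rate: float = 0.3,
    seed: int = 0,
    n_background_genes: int = 200,
    shift: float = 2.0,
    noise_sd: float = 0.5,
    baseline_hazard: float = 1.0 / 1500.0,
) -> BulkCohort:
    """Simulate a bulk expression cohort as lineage-profile mixtures with
    exponential survival under a proportional-hazards effect.

    Samples split into a high- and a low-infiltration group of equal size;
    blood-lineage content ``b`` is drawn from well-separated Beta
    distributions per group, blood-signature genes increase with ``b`` and
    microglial genes with ``1 - b``. Samples in the top half of planted
    blood content have their hazard multiplied by ``true_hr``. Age (mild
    log-linear hazard effect) and gender covariates are attached; censoring
    is exponential at a rate targeting ``censor_rate``.
    """
    if n_samples < 10:
        raise ValueError("n_samples < 10: survival stage unidentifiable")
    if true_hr <= 0:
        raise ValueError("true_hr must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    sig = signature[["gene", "lineage"]].reset_index(drop=True)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STAGE["bulk"],)))

    n_hi = n_samples // 2
    high = np.zeros(n_samples, dtype=bool)
    high[rng.permutation(n_samples)[:n_hi]] = True
    b = np.where(high, rng.beta(12, 4, n_samples), rng.beta(4, 12, n_samples))

    genes = list(sig.gene) + [f"B{i + 1:04d}" for i in range(n_background_genes)]
    base = rng.uniform(2.0, 8.0, len(genes))
    beta = np.zeros(len(genes))
    is_blood = np.array([ln == BLOOD for ln in sig.lineage])
    beta[: len(sig)] = np.where(is_blood, shift, -shift)
    # microglial genes track 1 - b: constant + negative slope on b
    offset = np.zeros(len(genes))
    offset[: len(sig)] = np.where(is_blood, 0.0, shift)

    expr = base[None, :] + offset[None, :] + beta[None, :] * b[:, None]
    expr = expr + rng.normal(0.0, noise_sd, expr.shape)
    expr = np.clip(expr, 0.0, None)  # log2(CPM+1) is non-negative

    age = np.clip(rng.normal(50.0, 12.0, n_samples), 20.0, 90.0)
    gender = rng.choice(["female", "male"], size=n_samples)
    subtype = rng.choice(["OLIG", "ASTRO", "GBM"], size=n_samples, p=[0.3, 0.3, 0.4])

    hazard = baseline_hazard * np.where(high, true_hr, 1.0) * np.exp(0.02 * (age - 50.0))
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        lam_c = hazard.mean() * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1.0)

    samples = [f"TCGA{i + 1:04d}" for i in range(n_samples)]
    expr_df = pd.DataFrame(expr, index=samples, columns=genes)
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "time": time,
            "event": event,
            "age": age,
            "gender": gender,
            "subtype": subtype,
        }
    ).set_index("sample_id", drop=False)
    clinical.index.name = None
    return BulkCohort(
        expr=expr_df,
        clinical=clinical,
        truth_blood_content=pd.Series(b, index=samples),
        truth_high_group=pd.Series(high, index=samples),
        true_hr=true_hr,
    )


# ---------------------------------------------------------------------------
# regional atlas
# ---------------------------------------------------------------------------

def simulate_regional_atlas(
    signature: pd.DataFrame,
    structures: Sequence[str] | None = None,
    enrichment: Mapping[str, float] | None = None,
    n_per_structure: int = 8,
    n_tumors: int = 10,
    n_background_genes: int = 100,
    tumor_sd: float = 0.25,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> RegionalAtlas:
    """Simulate a regional expression atlas with structure-specific lineage
    enrichment.

    ``enrichment`` maps structure to a signed blood bias (z units): positive
    values shift blood-signature genes up in that structure, negative values
    shift microglial genes up. A tumor-level random intercept is planted
    (samples from one tumor are correlated); samples are assigned to tumors
    round-robin within structures so tumors span structures, as in a
    microdissection design. The returned matrix is z-scored per gene.
    """
    if structures is None:
        structures = list(DEFAULT_STRUCTURES)
    if enrichment is None:
        enrichment = {s: DEFAULT_STRUCTURE_BIAS.get(s, 0.0) for s in structures}
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    if n_per_structure < 2:
        raise ValueError("need at least 2 samples per structure")
    sig = signature[["gene", "lineage"]].reset_index(drop=True)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STAGE["regional"],)))

    genes = list(sig.gene) + [f"R{i + 1:04d}" for i in range(n_background_genes)]
    is_blood = np.zeros(len(genes), dtype=bool)
    is_micro = np.zeros(len(genes), dtype=bool)
    is_blood[: len(sig)] = np.array([ln == BLOOD for ln in sig.lineage])
    is_micro[: len(sig)] = ~is_blood[: len(sig)]

    rows, labels, tumors = [], [], []
    tumor_effect = rng.normal(0.0, tumor_sd, n_tumors)
    for s in structures:
        bias = float(enrichment.get(s, 0.0))
        blood_shift = max(bias, 0.0)
        micro_shift = max(-bias, 0.0)
        for j in range(n_per_structure):
            tumor = j % n_tumors
            x = rng.normal(0.0, noise_sd, len(genes)) + tumor_effect[tumor]
            x[is_blood] += blood_shift
            x[is_micro] += micro_shift
            rows.append(x)
            labels.append(s)
            tumors.append(f"T{tumor + 1:02d}")
    X = np.asarray(rows)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    samples = [f"RS{i + 1:03d}" for i in range(len(rows))]
    return RegionalAtlas(
        expr=pd.DataFrame(X, index=samples, columns=genes),
        structures=pd.Series(labels, index=samples, name="structure"),
        tumors=pd.Series(tumors, index=samples, name="tumor"),
        truth_bias=dict(enrichment),
    )
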