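import numpy as np
import pandas as pd
import pytest

import tamont
from tamont import preprocess as pp
from tamont import signature as sig

# Reduced study used by unit tests: same structure as the default
# conditions, scaled down for speed. QC thresholds are scaled with the
# gene universe (800 genes cannot yield 800 detected genes).
SMALL = tamont.SimulationConfig(
    n_samples=6,
    n_cells_per_sample=120,
    n_genes=800,
    n_candidate_genes=120,
    n_true_signature=40,
    seed=7,
)
SMALL_QC = dict(min_genes=300, min_reads=20_000)


@pytest.fixture(scope="session")
def small_study() -> tamont.StudyData:
    return tamont.simulate_study(SMALL)


@pytest.fixture(scope="session")
def small_preprocessed(small_study) -> pp.PreprocessResult:
    return pp.run_preprocess(
        small_study.counts,
        small_study.cnv_segments,
        small_study.variants,
        **SMALL_QC,
    )


@pytest.fixture(scope="session")
def small_pipeline(small_study, small_preprocessed) -> sig.SignaturePipelineResult:
    tam = small_preprocessed.counts[
        small_preprocessed.annotation.cell_class == pp.TAM
    ].copy()
    return sig.derive_signature(
        tam, small_study.mouse_table, small_study.homology, seed=7
    )


@pytest.fixture(scope="session")
def generic_signature() -> pd.DataFrame:
    """A 66-gene signature frame for bulk/regional simulations."""
    return pd.DataFrame(
        {
            "gene": [f"SIG{i:03d}" for i in range(66)],
            "lineage": [tamont.BLOOD, tamont.MICROGLIA] * 33,
        }
    )


def make_counts(X, platforms=None, samples=None, gene_meta=None):
    """Small AnnData counts matrix with the metadata the pipeline expects."""
    import anndata as ad

    X = np.asarray(X)
    n, p = X.shape
    obs = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "sample_id": samples or ["S1"] * n,
            "platform": platforms or ["C1"] * n,
        },
        index=[f"c{i}" for i in range(n)],
    )
    if gene_meta is None:
        gene_meta = pd.DataFrame(
            {
                "gene_id": [f"g{j}" for j in range(p)],
                "symbol": [f"G{j}" for j in range(p)],
                "chrom": ["chr1"] * p,
                "start": np.arange(p) * 1_000_000,
                "end": np.arange(p) * 1_000_000 + 10_000,
            },
            index=[f"G{j}" for j in range(p)],
        )
    adata = ad.AnnData(X=X.astype(np.int32), obs=obs, var=gene_meta)
    adata.uns["scale"] = "counts"
    return adata
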