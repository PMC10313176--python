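import anndata as ad
import numpy as np
import pandas as pd
import pytest

from pnatlas.config import SyntheticConfig, p5_config
from pnatlas.sc_pipeline import normalize_log
from pnatlas.synthetic_data import simulate_counts, simulate_dataset


@pytest.fixture(scope="session")
def p5_counts() -> ad.AnnData:
    """Standard P5-style fixture: 6 subtypes, 3000 cells, seed 1."""
    return simulate_counts(p5_config(seed=1, n_cells_per_replicate=1500), "control")


@pytest.fixture(scope="session")
def p5_norm(p5_counts) -> ad.AnnData:
    return normalize_log(p5_counts)


@pytest.fixture(scope="session")
def e14_dataset() -> ad.AnnData:
    """E14.5-style control + mutant dataset, 2000 cells per genotype."""
    cfg = SyntheticConfig(seed=3, n_cells_per_replicate=1000, n_replicates_per_genotype=2)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def e14_norm(e14_dataset) -> ad.AnnData:
    return normalize_log(e14_dataset)


def toy_counts(counts: np.ndarray, mito_genes: list[int] | None = None) -> ad.AnnData:
    """Small hand-built count matrix with controllable mito flags."""
    counts = np.asarray(counts, dtype=np.int64)
    n_cells, n_genes = counts.shape
    is_mito = np.zeros(n_genes, dtype=bool)
    if mito_genes:
        is_mito[mito_genes] = True
    var = pd.DataFrame(
        {"is_mito": is_mito, "marker_of": [None] * n_genes},
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene"),
    )
    obs = pd.DataFrame(
        {
            "replicate": ["r0"] * n_cells,
            "genotype": ["control"] * n_cells,
        },
        index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell"),
    )
    return ad.AnnData(X=counts, obs=obs, var=var)
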