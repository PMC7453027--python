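import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import gutroadmap as gr
from gutroadmap import preprocess as pp


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated dataset (3 stages, 2 compartments, 42 clusters)."""
    return gr.simulate_dataset(gr.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A reduced configuration for fast multi-run tests."""
    return gr.SimulationConfig(
        clusters_per_stage=(2, 4, 8),
        cells_per_cluster=60,
        n_genes=700,
        n_markers_per_cluster=10,
        seed=0,
    )


@pytest.fixture(scope="session")
def stage3_lognorm(default_dataset):
    """Log-normalized stage-3 cells of the default dataset."""
    adata = default_dataset.adata
    a3 = adata[adata.obs["stage"] == "stage3"].copy()
    return pp.normalize_log(pp.filter_counts(a3))


def make_adata(counts, genes=None, cells=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = genes or [f"g{j}" for j in range(g)]
    cells = cells or [f"c{i}" for i in range(n)]
    return ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int32)),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
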