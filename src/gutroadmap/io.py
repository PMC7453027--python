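"""Reading and writing datasets as MTX + TSV + GMT + JSON file sets."""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datasets import GroundTruth, SimulatedDataset
from .signaling import PathwayGeneSets

__all__ = ["write_dataset", "read_dataset"]

_FILES = (
    "matrix.mtx",
    "genes.tsv",
    "barcodes.tsv",
    "cell_annotation.tsv",
    "ground_truth.json",
    "pathways.gmt",
)


def write_dataset(dataset: SimulatedDataset, out_dir, overwrite: bool = False) -> list[Path]:
    """Write a dataset as matrix.mtx (genes x cells, integer), TSVs, GMT, JSON.

    Refuses to overwrite existing files unless ``overwrite=True``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    existing = [f for f in _FILES if (out / f).exists()]
    if existing and not overwrite:
        raise FileExistsError(
            f"{existing} already exist in {out}; pass overwrite=True to replace"
        )
    adata = dataset.adata
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    mat = X.T.astype(np.int64).tocoo()  # genes x cells, MatrixMarket integer
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    pd.DataFrame({"gene": adata.var_names}).to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame({"barcode": adata.obs_names}).to_csv(
        out / "barcodes.tsv", sep="\t", index=False
    )
    adata.obs.to_csv(out / "cell_annotation.tsv", sep="\t", index_label="cell")
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(dataset.truth.to_serializable(), fh, indent=1)
    dataset.pathways.to_gmt(out / "pathways.gmt")
    return [out / f for f in _FILES]


def read_dataset(in_dir) -> SimulatedDataset:
    """Read a file set written by :func:`write_dataset`."""
    d = Path(in_dir)
    mat = scipy.io.mmread(str(d / "matrix.mtx"))
    X = sp.csr_matrix(mat.T).astype(np.int32)  # back to cells x genes
    genes = pd.read_csv(d / "genes.tsv", sep="\t")["gene"].astype(str)
    obs = pd.read_csv(d / "cell_annotation.tsv", sep="\t", index_col="cell")
    for col in ("stage", "compartment", "cluster"):
        if col in obs:
            obs[col] = obs[col].astype("category")
    adata = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    with open(d / "ground_truth.json", encoding="utf-8") as fh:
        truth = GroundTruth.from_serializable(json.load(fh))
    pathways = PathwayGeneSets.from_gmt(d / "pathways.gmt")
    return SimulatedDataset(adata=adata, truth=truth, pathways=pathways)
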