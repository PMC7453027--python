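"""QC, normalization, HVG selection, graph clustering, and marker detection.

A deliberately small pipeline in the style of the classic Seurat workflow:
count filtering (genes detected in >= 3 cells, cells with >= 100 detected
genes), global-scaling log-normalization (counts per ``scale_factor``,
log1p), dispersion-based highly-variable-gene selection, PCA + KNN graph +
Leiden community detection, and one-vs-rest Wilcoxon rank-sum marker tests
with Benjamini-Hochberg correction.  ``tf_code`` restricts the marker table
to a transcription-factor list to produce the per-cluster "TF code".

Cell-cycle regression and cross-stage anchor integration are intentionally
out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "QCParams",
    "filter_counts",
    "normalize_log",
    "select_hvg",
    "cluster_cells",
    "find_markers",
    "tf_code",
]


@dataclass(frozen=True)
class QCParams:
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 100
    max_genes_per_cell: int | None = None  # multiplet guard, off by default
    max_pct_mito: float | None = None  # mito guard, off by default
    scale_factor: float = 1e4
    n_hvg: int = 1500
    n_pcs: int = 20
    n_neighbors: int = 15
    cluster_resolution: float = 1.0

    def validate(self) -> None:
        if self.min_cells_per_gene < 0 or self.min_genes_per_cell < 0:
            raise ValueError("QC count thresholds must be >= 0")
        if self.scale_factor <= 0 or self.cluster_resolution <= 0:
            raise ValueError("scale_factor and cluster_resolution must be > 0")
        if self.n_pcs > self.n_hvg:
            raise ValueError("n_pcs must be <= n_hvg")


def filter_counts(adata: ad.AnnData, params: QCParams | None = None) -> ad.AnnData:
    """Drop rarely detected genes, then sparsely covered cells.

    Genes are filtered first (detected, i.e. count > 0, in >=
    ``min_cells_per_gene`` cells); the cell filter (>= ``min_genes_per_cell``
    detected genes) is applied on the gene-filtered matrix.  Both thresholds
    are inclusive.
    """
    if params is None:
        params = QCParams()
    params.validate()
    out = adata.copy()
    sc.pp.filter_genes(out, min_cells=params.min_cells_per_gene)
    if out.n_vars == 0:
        raise ValueError(
            f"no gene is detected in >= {params.min_cells_per_gene} cells"
        )
    sc.pp.filter_cells(out, min_genes=params.min_genes_per_cell)
    if params.max_genes_per_cell is not None:
        sc.pp.filter_cells(out, max_genes=params.max_genes_per_cell)
    if params.max_pct_mito is not None:
        mito = out.var_names.str.lower().str.startswith("mt-")
        counts = out.X.sum(axis=1).A1 if sp.issparse(out.X) else out.X.sum(axis=1)
        mito_counts = (
            out.X[:, mito].sum(axis=1).A1
            if sp.issparse(out.X)
            else out.X[:, mito].sum(axis=1)
        )
        frac = np.divide(mito_counts, counts, out=np.zeros_like(counts, dtype=float), where=counts > 0)
        out = out[frac <= params.max_pct_mito].copy()
    if out.n_obs == 0:
        raise ValueError(
            f"no cell has >= {params.min_genes_per_cell} detected genes"
        )
    return out


def normalize_log(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Counts-per-scale-factor log1p normalization; keeps counts in a layer."""
    out = adata.copy()
    X = out.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("cell(s) with zero total counts; run filter_counts first")
    out.layers["counts"] = X.copy()
    if sp.issparse(X):
        X = X.astype(float)
        X = sp.diags(scale_factor / totals) @ X
        X.data = np.log1p(X.data)
        out.X = X.tocsr()
    else:
        out.X = np.log1p(X.astype(float) / totals[:, None] * scale_factor)
    out.uns["normalize_log"] = {"scale_factor": scale_factor}
    return out


def select_hvg(adata: ad.AnnData, n_hvg: int = 1500) -> list[str]:
    """Top-``n_hvg`` genes by binned, standardized dispersion (Seurat flavor)."""
    if n_hvg > adata.n_vars:
        raise ValueError(f"n_hvg={n_hvg} exceeds the {adata.n_vars} genes present")
    tmp = adata.copy()
    sc.pp.highly_variable_genes(tmp, flavor="seurat", n_top_genes=n_hvg)
    return list(tmp.var_names[tmp.var["highly_variable"]])


def cluster_cells(
    adata: ad.AnnData, params: QCParams | None = None, seed: int = 0
) -> pd.Series:
    """PCA -> KNN graph -> Leiden labels on an HVG-restricted matrix.

    Returns consecutive integer labels indexed by cell; deterministic for a
    fixed seed.
    """
    if params is None:
        params = QCParams()
    params.validate()
    if adata.n_obs < params.n_pcs:
        raise ValueError(
            f"{adata.n_obs} cells is fewer than n_pcs={params.n_pcs}"
        )
    tmp = adata.copy()
    if sp.issparse(tmp.X):
        tmp.X = np.asarray(tmp.X.todense())
    sc.pp.scale(tmp, max_value=10)
    n_comps = min(params.n_pcs, tmp.n_vars - 1)
    sc.tl.pca(tmp, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(
        tmp,
        n_neighbors=min(params.n_neighbors, tmp.n_obs - 1),
        n_pcs=n_comps,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            tmp,
            resolution=params.cluster_resolution,
            random_state=seed,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
    codes = tmp.obs["leiden"].astype(int)
    # relabel to consecutive integers in order of first appearance
    remap = {old: new for new, old in enumerate(pd.unique(codes))}
    return pd.Series(
        [remap[c] for c in codes], index=adata.obs_names, name="cluster"
    )


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def find_markers(
    adata: ad.AnnData, labels, min_cells: int = 3
) -> pd.DataFrame:
    """One-vs-rest two-sided Wilcoxon rank-sum marker test per cluster.

    ``adata.X`` must hold log-normalized expression.  Log fold changes are
    computed on expm1-scale means with a pseudocount of 1 (log2).  P-values
    are Benjamini-Hochberg adjusted within each cluster.  Clusters with
    fewer than ``min_cells`` cells are skipped with a warning.
    """
    labels = pd.Series(labels, index=adata.obs_names)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("find_markers needs at least 2 clusters")
    X = _dense(adata.X)
    frames = []
    for cluster in clusters:
        mask = (labels == cluster).to_numpy()
        if mask.sum() < min_cells:
            warnings.warn(
                f"cluster {cluster!r} has fewer than {min_cells} cells; skipped",
                stacklevel=2,
            )
            continue
        x_in, x_out = X[mask], X[~mask]
        res = stats.mannwhitneyu(
            x_in, x_out, axis=0, alternative="two-sided", method="asymptotic"
        )
        mean_in = np.expm1(x_in).mean(axis=0)
        mean_out = np.expm1(x_out).mean(axis=0)
        lfc = np.log2((mean_in + 1) / (mean_out + 1))
        padj = stats.false_discovery_control(res.pvalue, method="bh")
        frames.append(
            pd.DataFrame(
                {
                    "cluster": cluster,
                    "gene": adata.var_names,
                    "log2fc": lfc,
                    "pct_in": (x_in > 0).mean(axis=0),
                    "pct_out": (x_out > 0).mean(axis=0),
                    "pvalue": res.pvalue,
                    "padj": padj,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def tf_code(
    markers: pd.DataFrame,
    tf_list,
    top_n: int = 5,
    max_padj: float = 0.05,
    min_log2fc: float = 0.25,
) -> dict:
    """Top-``top_n`` marker transcription factors per cluster.

    The marker table is restricted to ``tf_list`` and to significant,
    up-regulated rows, then ranked by adjusted p-value and (descending) fold
    change, with ties broken lexicographically by gene name.  Clusters with
    no TF markers map to an empty list.
    """
    if len(list(tf_list)) == 0:
        raise ValueError("tf_list must be non-empty")
    tfs = set(tf_list)
    out: dict = {}
    for cluster, sub in markers.groupby("cluster"):
        sub = sub[
            sub["gene"].isin(tfs)
            & (sub["padj"] <= max_padj)
            & (sub["log2fc"] >= min_log2fc)
        ]
        sub = sub.sort_values(
            ["padj", "log2fc", "gene"], ascending=[True, False, True], kind="mergesort"
        )
        out[cluster] = list(sub["gene"].head(top_n))
    return out
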