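"""Cross-modality enrichment of a perturbation gene list in cell clusters.

Given a genes-by-clusters average-expression matrix and an externally
derived up/down gene list (e.g. transcripts responding to loss of a
signaling pathway in a bulk experiment), two summaries are provided:

* min-max row normalization of the cluster averages (heatmap values);
* a GSEA-style weighted Kolmogorov-Smirnov enrichment score per cluster,
  where genes are ranked by cluster specificity (cluster mean minus the
  mean of all other clusters) and significance comes from gene-label
  permutations with a +1 correction, so p-values are never exactly zero.

The permutation p-value measures how extreme the observed running-sum
deviation is in magnitude (|ES_perm| >= |ES_obs|); the direction of the
enrichment is carried by the sign of the ES itself.  This keeps null
p-values uniform and lets a maximally enriched set reach exactly
1/(n_permutations + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["GseaResult", "minmax_rows", "gsea_score", "cluster_enrichment"]


def minmax_rows(avg: pd.DataFrame) -> pd.DataFrame:
    """Map each row through (x - min) / (max - min); constant rows -> 0."""
    arr = avg.to_numpy(dtype=float)
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span.ravel() == 0
    if constant.any():
        logger.info("minmax_rows: %d constant row(s) mapped to 0", constant.sum())
    span[span == 0] = 1.0
    out = (arr - lo) / span
    out[constant] = 0.0
    return pd.DataFrame(out, index=avg.index, columns=avg.columns)


@dataclass
class GseaResult:
    es: float
    pvalue: float
    n_hits: int
    n_permutations: int
    degenerate: bool = False


def _running_es(weights: np.ndarray, hits: np.ndarray) -> float:
    """Signed extremum of the weighted KS running sum for one hit vector."""
    n = hits.size
    n_hits = int(hits.sum())
    hit_w = weights * hits
    denom = hit_w.sum()
    if denom == 0:  # all hit statistics are zero: fall back to equal weights
        hit_w = hits.astype(float)
        denom = float(n_hits)
    p_hit = np.cumsum(hit_w) / denom
    n_miss = n - n_hits
    p_miss = np.cumsum(1.0 - hits) / n_miss
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def gsea_score(
    ranked_genes: pd.Series,
    gene_set,
    weight: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Weighted KS enrichment score of ``gene_set`` in a ranked gene list.

    ``ranked_genes`` maps gene -> ranking statistic; genes are sorted by
    descending statistic (ties broken by gene name for determinism).  Hit
    increments are proportional to |statistic|^weight, miss decrements are
    uniform, and the ES is the signed extremum of the running sum.  The
    p-value is the fraction of ``n_permutations`` random gene-label
    permutations whose extremum is at least as extreme in magnitude as the
    observed ES, with a +1 correction.

    A gene set covering every ranked gene has no misses; the ES is then
    defined as 1 and flagged degenerate.
    """
    stats_ser = pd.Series(ranked_genes, dtype=float)
    order = sorted(stats_ser.index, key=lambda g: (-stats_ser[g], g))
    stats_sorted = stats_ser.loc[order]
    genes = np.array(order)
    hits = np.isin(genes, list(gene_set)).astype(float)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene_set does not intersect the ranked gene list")
    n = len(genes)
    if n_hits == n:
        return GseaResult(
            es=1.0, pvalue=1.0, n_hits=n_hits,
            n_permutations=n_permutations, degenerate=True,
        )
    weights = np.abs(stats_sorted.to_numpy()) ** weight
    es = _running_es(weights, hits)

    rng = np.random.default_rng(seed)
    count = 0
    base = hits.copy()
    for _ in range(n_permutations):
        perm = rng.permutation(base)
        es_p = _running_es(weights, perm)
        count += abs(es_p) >= abs(es)
    pvalue = (1 + count) / (n_permutations + 1)
    return GseaResult(
        es=es, pvalue=pvalue, n_hits=n_hits,
        n_permutations=n_permutations, degenerate=False,
    )


def cluster_enrichment(
    avg: pd.DataFrame,
    up_set,
    down_set,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster enrichment of the up and down gene sets.

    For each cluster, genes are ranked by specificity (that cluster's mean
    minus the mean of all other clusters) and both sets are scored with
    :func:`gsea_score`.  P-values are Benjamini-Hochberg adjusted across
    clusters separately for each set.
    """
    universe = set(avg.index)
    for name, s in (("up", up_set), ("down", down_set)):
        if not universe & set(s):
            raise ValueError(f"{name}_set does not intersect the gene universe")
    rows = []
    clusters = list(avg.columns)
    rng = np.random.default_rng(seed)
    for cluster in clusters:
        rest = avg.drop(columns=cluster).mean(axis=1)
        spec = avg[cluster] - rest
        cluster_seed = int(rng.integers(2**31 - 1))  # shared by both sets
        for set_name, gene_set in (("up", up_set), ("down", down_set)):
            res = gsea_score(
                spec,
                gene_set,
                n_permutations=n_permutations,
                seed=cluster_seed,
            )
            rows.append(
                {
                    "cluster": cluster,
                    "set": set_name,
                    "es": res.es,
                    "pvalue": res.pvalue,
                    "n_hits": res.n_hits,
                }
            )
    out = pd.DataFrame(rows)
    out["padj"] = np.nan
    for set_name in ("up", "down"):
        mask = out["set"] == set_name
        out.loc[mask, "padj"] = stats.false_discovery_control(
            out.loc[mask, "pvalue"], method="bh"
        )
    return out.set_index(["cluster", "set"])
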