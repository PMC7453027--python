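"""Pseudo-spatial ordering by diffusion-map flood pseudotime.

For cells forming a continuous positional field (for instance an
anterior-posterior axis in a tube of embryonic tissue), transcriptional
distance tracks positional distance, so a pseudotime computed from a root at
one end of the field orders cell populations along the axis - a proxy of
pseudo-space rather than developmental time.

The pipeline: a Gaussian-kernel Markov matrix over cells is
eigendecomposed (diffusion map); a KNN graph is built in the space of the
first ``n_dc`` diffusion components with edge weights renormalized to
transition probabilities; then a probabilistic breadth-first "flood" is
simulated repeatedly from the root cells, and each cell's pseudotime is its
average first-visit iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "DiffusionGraph",
    "PseudotimeResult",
    "transition_from_kernel",
    "build_diffusion_graph",
    "flood_pseudotime",
    "order_clusters",
]

_EPS = 1e-300


def transition_from_kernel(kernel: np.ndarray) -> np.ndarray:
    """Row-normalize a (symmetric, non-negative) affinity kernel."""
    kernel = np.asarray(kernel, dtype=float)
    if (kernel < 0).any():
        raise ValueError("kernel must be non-negative")
    rowsum = kernel.sum(axis=1)
    if (rowsum == 0).any():
        raise ValueError("kernel has an all-zero row")
    return kernel / rowsum[:, None]


@dataclass
class DiffusionGraph:
    """Cells, diffusion-component coordinates and the transition matrix."""

    cells: pd.Index
    components: np.ndarray
    transition: sp.csr_matrix
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.cells = pd.Index(self.cells)
        self.transition = sp.csr_matrix(self.transition)
        if self.transition.shape[0] != len(self.cells):
            raise ValueError("transition shape does not match the cell list")
        if (self.transition.data < 0).any():
            raise ValueError("transition probabilities must be >= 0")
        rowsum = np.asarray(self.transition.sum(axis=1)).ravel()
        if np.abs(rowsum - 1).max() > 1e-9:
            raise ValueError("transition rows must sum to 1 (+/- 1e-9)")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _adaptive_kernel(D2: np.ndarray, k: int) -> np.ndarray:
    """Gaussian kernel with per-point bandwidth = distance to k-th neighbor."""
    D = np.sqrt(D2)
    order = np.sort(D, axis=1)
    sigma = order[:, min(k, D.shape[1] - 1)]
    sigma = np.maximum(sigma, 1e-12)
    return np.exp(-D2 / np.outer(sigma, sigma))


def build_diffusion_graph(
    expr,
    n_dc: int = 8,
    k_neighbors: int = 15,
    seed: int = 0,
) -> DiffusionGraph:
    """Diffusion-map embedding + KNN transition graph.

    ``expr`` is an AnnData (normalized expression in ``.X``) or a dense
    cells-by-features array.  The first ``n_dc`` non-trivial diffusion
    components of the Gaussian-kernel Markov matrix define the embedding;
    a KNN graph in that space carries Gaussian edge weights renormalized to
    per-row transition probabilities.  Raises if the KNN graph is
    disconnected, listing component sizes.
    """
    try:
        X = expr.X
        cells = pd.Index(expr.obs_names)
    except AttributeError:
        X = expr
        cells = pd.RangeIndex(np.asarray(X).shape[0])
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(f"need >= k_neighbors+1={k_neighbors + 1} cells, got {n}")

    D2 = squareform(pdist(X, metric="sqeuclidean"))
    K = _adaptive_kernel(D2, k_neighbors)
    # symmetric-normalized eigendecomposition of the Markov matrix
    d = K.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d + _EPS)
    A = K * np.outer(inv_sqrt, inv_sqrt)
    evals, evecs = np.linalg.eigh(A)
    idx = np.argsort(evals)[::-1][: n_dc + 1]
    evals, evecs = evals[idx], evecs[:, idx]
    phi = evecs * inv_sqrt[:, None]
    # drop the trivial (constant) component; scale by eigenvalue
    comps = phi[:, 1 : n_dc + 1] * evals[1 : n_dc + 1]
    # deterministic sign: largest-magnitude entry positive
    for j in range(comps.shape[1]):
        i = np.argmax(np.abs(comps[:, j]))
        if comps[i, j] < 0:
            comps[:, j] *= -1

    nn = NearestNeighbors(n_neighbors=min(k_neighbors + 1, n)).fit(comps)
    dist, ind = nn.kneighbors(comps)
    dist, ind = dist[:, 1:], ind[:, 1:]  # drop self
    sigma = np.maximum(dist[:, -1], 1e-12)
    rows = np.repeat(np.arange(n), ind.shape[1])
    cols = ind.ravel()
    w = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    W = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)

    n_comp, labels = connected_components(W, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(
            f"KNN graph is disconnected into {n_comp} components "
            f"(sizes {sizes}); increase k_neighbors"
        )
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    P = sp.diags(1.0 / rowsum) @ W
    return DiffusionGraph(
        cells=cells, components=comps, transition=P.tocsr(), eigenvalues=evals
    )


@dataclass
class PseudotimeResult:
    """Per-cell average first-visit iteration of the flood simulations."""

    pseudotime: pd.Series
    n_simulations: int
    root_cells: pd.Index
    per_simulation_var: pd.Series | None = None

    def cluster_summary(self, labels) -> pd.DataFrame:
        labels = pd.Series(labels, index=self.pseudotime.index)
        g = self.pseudotime.groupby(labels, observed=True)
        return pd.DataFrame(
            {
                "median": g.median(),
                "q25": g.quantile(0.25),
                "q75": g.quantile(0.75),
                "mean": g.mean(),
            }
        )


def flood_pseudotime(
    graph: DiffusionGraph,
    root_cells,
    n_simulations: int = 50,
    seed: int = 0,
) -> PseudotimeResult:
    """Probabilistic breadth-first flood from the root cells.

    Per simulation, iteration t visits each unvisited neighbor of the
    visited set with probability equal to its maximum transition
    probability from any visited neighbor; if an iteration visits no new
    cell, the frontier cell with the highest such probability is
    force-visited so the flood always terminates.  Pseudotime is the mean
    first-visit iteration over simulations (roots are iteration 0).
    """
    roots = pd.Index(root_cells)
    if len(roots) == 0:
        raise ValueError("root_cells must be non-empty")
    root_pos = graph.cells.get_indexer(roots)
    if (root_pos < 0).any():
        missing = list(roots[root_pos < 0])
        raise ValueError(f"root cell(s) not in graph: {missing}")
    n = graph.n_cells
    P = graph.transition
    rng = np.random.default_rng(seed)

    total = np.zeros(n)
    total_sq = np.zeros(n)
    for _ in range(n_simulations):
        visited = np.zeros(n, dtype=bool)
        best = np.zeros(n)  # max transition prob from the visited set
        first_visit = np.zeros(n)
        newly = list(root_pos)
        visited[root_pos] = True
        it = 0
        while True:
            for v in newly:
                lo, hi = P.indptr[v], P.indptr[v + 1]
                nbr = P.indices[lo:hi]
                np.maximum.at(best, nbr, P.data[lo:hi])
            best[visited] = 0.0
            frontier = np.flatnonzero(best > 0)
            if frontier.size == 0:
                break
            it += 1
            draws = rng.random(frontier.size)
            hit = frontier[draws < best[frontier]]
            if hit.size == 0:
                # force-visit the most reachable frontier cell
                hit = frontier[[np.argmax(best[frontier])]]
            visited[hit] = True
            first_visit[hit] = it
            newly = list(hit)
        if not visited.all():
            raise ValueError("graph is disconnected; flood could not reach all cells")
        total += first_visit
        total_sq += first_visit**2
    mean = total / n_simulations
    var = total_sq / n_simulations - mean**2
    return PseudotimeResult(
        pseudotime=pd.Series(mean, index=graph.cells, name="pseudotime"),
        n_simulations=n_simulations,
        root_cells=roots,
        per_simulation_var=pd.Series(var, index=graph.cells, name="var"),
    )


def order_clusters(result: PseudotimeResult, labels) -> list:
    """Clusters sorted by median pseudotime (ties: mean, then label)."""
    labels = pd.Series(labels, index=result.pseudotime.index)
    if labels.isna().any():
        raise ValueError("every cell must be labeled")
    # stable sort on a label-sorted frame => label breaks remaining ties
    summary = result.cluster_summary(labels).sort_index()
    summary = summary.sort_values(["median", "mean"], kind="mergesort")
    return list(summary.index)
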