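"""Pathway metagene profiling and receptor-ligand signaling-roadmap inference.

A *metagene* collapses a pathway gene set (ligands, receptors, or
context-independent response genes) into one per-cell scalar in [0, 1]:

1. each gene's counts are divided by that gene's maximum count over all
   cells in the analysis universe (epithelial + mesenchymal cells together);
2. the normalized values are summed per cell;
3. the per-cell sums are divided by their maximum.

Cluster-level profiles are the per-cluster average metagene, z-scored across
clusters and clipped to [-2, 2] (dot-plot scaling), together with the
fraction of cells with metagene > 0.  A cluster is called a sender /
receiver / responder when its scaled metagene is >= -1 (Notch ligand: >=
-1.5, which compensates for the uniformly low Notch ligand expression) *and*
at least 25% of its cells express the metagene.  Signaling edges connect
senders to responding receivers: autocrine when the responder itself sends,
paracrine when a spatially adjacent cluster (same tissue layer within a
window, or the apposed cluster of the other layer) sends.  Edge strength is
the sum of the sender's scaled ligand metagene and the responder's scaled
response metagene; a strength >= 1 is classed "strong".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGeneSets",
    "SpatialLayout",
    "Thresholds",
    "compute_metagene",
    "metagene_matrix",
    "summarize_clusters",
    "call_senders_responders",
    "infer_edges",
    "export_roadmap",
]

ROLES = ("ligand", "receptor", "response")


@dataclass
class PathwayGeneSets:
    """Per-pathway ligand / receptor / response gene lists.

    ``sets`` maps pathway name -> {role -> gene list}.  Roles must be
    disjoint within a pathway.
    """

    sets: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        for p, roles in self.sets.items():
            for role in roles:
                if role not in ROLES:
                    raise ValueError(f"unknown role {role!r} in pathway {p!r}")
            seen: dict[str, str] = {}
            for role in ROLES:
                for g in roles.get(role, []):
                    if g in seen and seen[g] != role:
                        raise ValueError(
                            f"gene {g!r} appears as both {seen[g]} and {role} "
                            f"in pathway {p!r}"
                        )
                    seen[g] = role

    @property
    def pathways(self) -> list[str]:
        return list(self.sets)

    def genes(self, pathway: str, role: str) -> list[str]:
        return list(self.sets[pathway].get(role, []))

    def to_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for p in self.sets:
                for role in ROLES:
                    genes = self.sets[p].get(role, [])
                    if not genes:
                        continue
                    fh.write(
                        "\t".join([f"{p}_{role}", f"{p} {role} genes", *genes])
                        + "\n"
                    )

    @classmethod
    def from_gmt(cls, path) -> "PathwayGeneSets":
        sets: dict[str, dict[str, list[str]]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                name, _desc, *genes = line.split("\t")
                pathway, _, role = name.rpartition("_")
                if not pathway or role not in ROLES:
                    raise ValueError(
                        f"GMT set name {name!r} is not of the form "
                        "<PATHWAY>_ligand|_receptor|_response"
                    )
                sets.setdefault(pathway, {})[role] = list(genes)
        return cls(sets)


def _dense_counts(counts, gene_names=None):
    """Return (cells x genes ndarray, gene index) from AnnData or array."""
    try:  # AnnData duck-typing
        X = counts.X
        names = pd.Index(counts.var_names)
    except AttributeError:
        X = counts
        if gene_names is None:
            raise ValueError("gene_names is required for array input")
        names = pd.Index(gene_names)
    if sp.issparse(X):
        X = np.asarray(X.todense())
    else:
        X = np.asarray(X)
    return X.astype(float), names


def compute_metagene(counts, genes, gene_names=None) -> np.ndarray:
    """Three-step max-normalized metagene over ``genes`` for every cell.

    ``counts`` is an AnnData (raw counts in ``.X``) or a cells-by-genes
    array with ``gene_names``.  The normalization universe is exactly the
    set of cells passed in, so the caller must pass the union of all cells
    the profile is meant to be comparable across.

    Genes absent from the matrix or with an all-zero column are dropped
    (logged); an empty effective gene list yields an all-zero metagene with
    a warning rather than an error.
    """
    X, names = _dense_counts(counts, gene_names)
    idx = names.get_indexer([g for g in genes if g in names])
    idx = idx[idx >= 0]
    if len(idx) < len(list(genes)):
        logger.info(
            "compute_metagene: %d of %d genes absent from the matrix",
            len(list(genes)) - len(idx),
            len(list(genes)),
        )
    sub = X[:, idx]
    colmax = sub.max(axis=0) if sub.size else np.array([])
    keep = colmax > 0
    if keep.size and keep.sum() < keep.size:
        logger.info(
            "compute_metagene: dropping %d genes with zero max count",
            int((~keep).sum()),
        )
    sub = sub[:, keep]
    if sub.shape[1] == 0:
        warnings.warn(
            "compute_metagene: no effective genes; returning zeros",
            stacklevel=2,
        )
        return np.zeros(X.shape[0])
    norm = sub / sub.max(axis=0)  # step 1
    summed = norm.sum(axis=1)  # step 2
    m = summed.max()  # step 3
    return summed / m if m > 0 else summed


def metagene_matrix(counts, pathway_sets: PathwayGeneSets, gene_names=None) -> pd.DataFrame:
    """Cells x (pathway, role) metagene table; columns are a MultiIndex."""
    X, names = _dense_counts(counts, gene_names)
    try:
        index = pd.Index(counts.obs_names, name="cell")
    except AttributeError:
        index = pd.RangeIndex(X.shape[0], name="cell")
    cols = {}
    for p in pathway_sets.pathways:
        for role in ROLES:
            cols[(p, role)] = compute_metagene(
                X, pathway_sets.genes(p, role), gene_names=names
            )
    out = pd.DataFrame(cols, index=index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["pathway", "role"])
    return out


def summarize_clusters(metagenes: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-(cluster, pathway, role) mean, dot-plot-scaled mean, and % expressing.

    The scaled mean is the z-score of the cluster means across all clusters
    for that (pathway, role) column (sample sd, ddof=1), clipped to [-2, 2];
    a column with identical cluster means scales to 0.
    """
    labels = pd.Series(labels, index=metagenes.index)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError(
            "summarize_clusters needs at least 2 clusters; z-scoring across a "
            "single cluster is undefined -- use the raw means instead"
        )
    grouped = metagenes.groupby(labels, observed=True)
    means = grouped.mean().loc[clusters]
    pct = grouped.apply(lambda df: (df > 0).mean()).loc[clusters]
    sd = means.std(axis=0, ddof=1)
    centered = means - means.mean(axis=0)
    scaled = centered.div(sd.where(sd > 0, np.inf), axis=1).clip(-2, 2)
    rows = []
    for cluster in clusters:
        for p, role in metagenes.columns:
            rows.append(
                {
                    "cluster": cluster,
                    "pathway": p,
                    "role": role,
                    "mean": means.loc[cluster, (p, role)],
                    "scaled": scaled.loc[cluster, (p, role)],
                    "pct_expressing": pct.loc[cluster, (p, role)],
                }
            )
    return pd.DataFrame(rows).set_index(["cluster", "pathway", "role"])


@dataclass(frozen=True)
class Thresholds:
    """Sender/receiver/responder calling thresholds on the dot-plot scale."""

    mean: float = -1.0
    pct: float = 0.25
    ligand_mean_override: dict = field(
        default_factory=lambda: {"Notch": -1.5}
    )


def call_senders_responders(
    profile: pd.DataFrame, thresholds: Thresholds | None = None
) -> pd.DataFrame:
    """Boolean can_send / can_receive / is_responding per (cluster, pathway).

    All comparisons are inclusive: a scaled mean of exactly -1 with exactly
    25% of cells expressing passes.
    """
    explicit = thresholds is not None
    if thresholds is None:
        thresholds = Thresholds()
    pathways = sorted(profile.index.get_level_values("pathway").unique())
    unknown = set(thresholds.ligand_mean_override) - set(pathways)
    if unknown and explicit:
        raise ValueError(
            f"ligand threshold override for unknown pathway(s): {sorted(unknown)}"
        )
    clusters = sorted(profile.index.get_level_values("cluster").unique())
    rows = []
    for cluster in clusters:
        for p in pathways:
            lig = profile.loc[(cluster, p, "ligand")]
            rec = profile.loc[(cluster, p, "receptor")]
            res = profile.loc[(cluster, p, "response")]
            lig_thr = thresholds.ligand_mean_override.get(p, thresholds.mean)
            rows.append(
                {
                    "cluster": cluster,
                    "pathway": p,
                    "can_send": bool(
                        lig["scaled"] >= lig_thr
                        and lig["pct_expressing"] >= thresholds.pct
                    ),
                    "can_receive": bool(
                        rec["scaled"] >= thresholds.mean
                        and rec["pct_expressing"] >= thresholds.pct
                    ),
                    "is_responding": bool(
                        res["scaled"] >= thresholds.mean
                        and res["pct_expressing"] >= thresholds.pct
                    ),
                }
            )
    return pd.DataFrame(rows).set_index(["cluster", "pathway"])


@dataclass
class SpatialLayout:
    """A-P-ordered cluster lists per tissue layer plus an adjacency window.

    ``layers`` maps layer name (e.g. ``"DE"``/``"SM"``) to the ordered list
    of clusters along the anterior-posterior axis.  Two clusters are
    adjacent when they sit within ``window`` ranks of each other, either in
    the same layer or across layers (apposition = equal rank, +/- window).
    """

    layers: dict[str, list[str]]
    window: int = 1

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for layer, clusters in self.layers.items():
            dup = seen & set(clusters)
            if dup:
                raise ValueError(
                    f"cluster(s) {sorted(dup)} appear in more than one layer"
                )
            seen |= set(clusters)
        self._layer_of = {
            c: layer for layer, cs in self.layers.items() for c in cs
        }
        self._rank_of = {
            c: r for cs in self.layers.values() for r, c in enumerate(cs)
        }

    @classmethod
    def from_positions(
        cls, compartment: dict[str, str], position: dict[str, float], window: int = 1
    ) -> "SpatialLayout":
        layers: dict[str, list[str]] = {}
        for layer in sorted(set(compartment.values())):
            members = [c for c in position if compartment[c] == layer]
            members.sort(key=lambda c: (position[c], c))
            layers[layer] = members
        return cls(layers=layers, window=window)

    def layer(self, cluster: str) -> str:
        return self._layer_of[cluster]

    def rank(self, cluster: str) -> int:
        return self._rank_of[cluster]

    @property
    def clusters(self) -> list[str]:
        return [c for cs in self.layers.values() for c in cs]

    def neighbors(self, cluster: str) -> list[str]:
        """All clusters adjacent to ``cluster`` (same layer or apposed)."""
        layer, rank = self.layer(cluster), self.rank(cluster)
        out = []
        for other_layer, members in self.layers.items():
            for c in members:
                if c == cluster:
                    continue
                dr = abs(self.rank(c) - rank)
                if dr <= self.window:
                    out.append(c)
        return out


def infer_edges(
    flags: pd.DataFrame, profile: pd.DataFrame, layout: SpatialLayout
) -> pd.DataFrame:
    """Autocrine/paracrine signaling edges from caller flags and the layout.

    For every cluster R that is responding *and* can receive pathway p: an
    autocrine edge (R -> R) when R itself can send p, and a paracrine edge
    (S -> R) for every adjacent sender S != R.  Strength is sender scaled
    ligand + responder scaled response; strong iff >= 1.  Edges are sorted
    by (pathway, responder, sender).
    """
    missing = set(flags.index.get_level_values("cluster")) - set(layout.clusters)
    if missing:
        raise ValueError(f"layout does not cover cluster(s): {sorted(missing)}")
    edges = []
    for (cluster, pathway), row in flags.sort_index().iterrows():
        if not (row["is_responding"] and row["can_receive"]):
            continue
        response_scaled = profile.loc[(cluster, pathway, "response"), "scaled"]
        senders = []
        if row["can_send"]:
            senders.append((cluster, "autocrine"))
        for s in layout.neighbors(cluster):
            if flags.loc[(s, pathway), "can_send"]:
                senders.append((s, "paracrine"))
        for sender, mode in senders:
            strength = (
                profile.loc[(sender, pathway, "ligand"), "scaled"]
                + response_scaled
            )
            edges.append(
                {
                    "pathway": pathway,
                    "sender": sender,
                    "responder": cluster,
                    "mode": mode,
                    "strength": float(strength),
                    "strength_class": "strong" if strength >= 1 else "normal",
                }
            )
    out = pd.DataFrame(
        edges,
        columns=["pathway", "sender", "responder", "mode", "strength", "strength_class"],
    )
    return out.sort_values(["pathway", "responder", "sender"]).reset_index(drop=True)


def export_roadmap(
    edges: pd.DataFrame,
    profile: pd.DataFrame,
    tree,
    thresholds: Thresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join per-cluster pathway responses onto a cell-state tree.

    Returns (node table, edge table).  Each tree node lists, alphabetically,
    the pathways it responds to and the subset with a strong incoming edge
    (the "letters at each step" representation).  Clusters with signaling
    flags but no tree node are emitted unattached with a warning.
    """
    flags = call_senders_responders(profile, thresholds)
    tree_clusters = {cluster: stage for stage, cluster in tree.nodes}
    rows = []
    clusters = sorted(flags.index.get_level_values("cluster").unique())
    loose = [c for c in clusters if c not in tree_clusters]
    if loose:
        warnings.warn(
            f"cluster(s) {loose} are missing from the tree; emitted unattached",
            stacklevel=2,
        )
    strong_by_responder: dict[tuple[str, str], bool] = {}
    for _, e in edges.iterrows():
        key = (e["responder"], e["pathway"])
        strong_by_responder[key] = (
            strong_by_responder.get(key, False) or e["strength_class"] == "strong"
        )
    for cluster in clusters:
        sub = flags.xs(cluster, level="cluster")
        responding = sorted(sub.index[sub["is_responding"] & sub["can_receive"]])
        strong = sorted(
            p for p in responding if strong_by_responder.get((cluster, p), False)
        )
        rows.append(
            {
                "stage": tree_clusters.get(cluster),
                "cluster": cluster,
                "responding": ",".join(responding),
                "strong": ",".join(strong),
            }
        )
    nodes = pd.DataFrame(rows, columns=["stage", "cluster", "responding", "strong"])
    return nodes, edges.copy()
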