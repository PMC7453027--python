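"""Stage-layered cell-state trees by parent-child single-cell KNN voting.

Each cell of a later stage votes for its most likely parent cluster at the
preceding stage: a KNN classifier trained on the earlier stage's cells
(features = union of the distinguishing marker genes of both stages) returns
per-cell vote probabilities over parent clusters.  Votes are averaged per
child cluster, normalized for parent cluster size, and expressed as % of
total votes.  The top choice per child cluster becomes a solid tree edge;
a second choice with more than 60% of the winning vote share is "prominent"
and drawn dashed.  A hard-vote variant (each cell casts one vote for its
KNN-majority parent) cross-checks the soft tabulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "VoteMatrix",
    "StateTree",
    "build_feature_matrix",
    "knn_vote",
    "tabulate_votes",
    "hard_vote_confusion",
    "top_choices",
    "build_tree",
    "compare_tabulations",
]


@dataclass
class VoteMatrix:
    """Child-cluster x parent-cluster vote shares in % (rows sum to 100)."""

    table: pd.DataFrame
    k: int = 0
    mode: str = "size_normalized"
    features: list[str] = field(default_factory=list)
    child_stage: str | None = None
    parent_stage: str | None = None

    def __post_init__(self) -> None:
        t = self.table
        if (t.to_numpy() < -1e-12).any():
            raise ValueError("vote shares must be >= 0")
        rowsum = t.sum(axis=1)
        if np.abs(rowsum - 100).max() > 1e-6:
            raise ValueError("vote-matrix rows must sum to 100% (+/- 1e-6)")


def _marker_union(markers) -> list[str]:
    """Sorted union of marker genes from a MarkerTable or cluster->genes dict."""
    if isinstance(markers, pd.DataFrame):
        return sorted(set(markers["gene"]))
    if isinstance(markers, dict):
        return sorted({g for genes in markers.values() for g in genes})
    return sorted(set(markers))


def build_feature_matrix(
    expr_parent, expr_child, markers
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Restrict both stages to the shared marker-gene features.

    ``markers`` may be a marker table (with a ``gene`` column), a mapping
    cluster -> gene list, or a plain gene list; the union is taken, genes
    absent from either stage are dropped with a log message, and both
    matrices are returned with identical (sorted) gene order.
    """
    union = _marker_union(markers)
    parent_genes = set(expr_parent.var_names)
    child_genes = set(expr_child.var_names)
    kept = [g for g in union if g in parent_genes and g in child_genes]
    if not kept:
        raise ValueError("no marker gene is present in both stages")
    if len(kept) < len(union):
        logger.warning(
            "build_feature_matrix: %d of %d marker genes absent from one "
            "stage and dropped",
            len(union) - len(kept),
            len(union),
        )
    fp = expr_parent[:, kept].to_df()
    fc = expr_child[:, kept].to_df()
    return fp, fc, kept


def knn_vote(
    parent_features: pd.DataFrame,
    parent_labels,
    child_features: pd.DataFrame,
    k: int = 5,
) -> pd.DataFrame:
    """Per-child-cell vote probabilities over parent clusters.

    Each child cell's probability on parent cluster P is the fraction of its
    k nearest parent cells (Euclidean distance in feature space) that belong
    to P.  Distance ties are broken by parent cell index.
    """
    Xp = parent_features.to_numpy(dtype=float)
    Xc = child_features.to_numpy(dtype=float)
    if np.isnan(Xp).any() or np.isnan(Xc).any():
        raise ValueError("feature matrices contain NaN")
    if k > Xp.shape[0]:
        raise ValueError(f"k={k} exceeds the {Xp.shape[0]} parent cells")
    labels = pd.Series(parent_labels, index=parent_features.index)
    clusters = sorted(labels.unique())
    codes = labels.map({c: i for i, c in enumerate(clusters)}).to_numpy()

    D = cdist(Xc, Xp)
    nearest = np.argsort(D, axis=1, kind="stable")[:, :k]
    votes = codes[nearest]
    probs = np.stack(
        [(votes == i).mean(axis=1) for i in range(len(clusters))], axis=1
    )
    return pd.DataFrame(probs, index=child_features.index, columns=clusters)


def tabulate_votes(
    cell_probs: pd.DataFrame,
    child_labels,
    parent_cluster_sizes,
    mode: str = "size_normalized",
    **meta,
) -> VoteMatrix:
    """Average per-cell vote probabilities into a % vote matrix.

    In ``size_normalized`` mode each parent cluster's column is divided by
    that cluster's cell fraction (its share of all parent cells) before
    rows are renormalized to 100%; ``raw`` mode skips the division.
    """
    if mode not in ("size_normalized", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    child_labels = pd.Series(child_labels, index=cell_probs.index)
    if child_labels.isna().any():
        raise ValueError("every child cell must be labeled")
    sizes = pd.Series(parent_cluster_sizes).reindex(cell_probs.columns)
    if sizes.isna().any() or (sizes <= 0).any():
        bad = list(sizes.index[sizes.isna() | (sizes <= 0)])
        raise ValueError(f"parent cluster(s) with zero/unknown size: {bad}")
    avg = cell_probs.groupby(child_labels, observed=True).mean()
    if mode == "size_normalized":
        avg = avg / (sizes / sizes.sum())
    table = avg.div(avg.sum(axis=1), axis=0) * 100.0
    table = table.sort_index()
    return VoteMatrix(table=table, mode=mode, **meta)


def hard_vote_confusion(
    parent_features: pd.DataFrame,
    parent_labels,
    child_features: pd.DataFrame,
    child_labels,
    k: int = 5,
    mode: str = "size_normalized",
    **meta,
) -> VoteMatrix:
    """Confusion-matrix tabulation where each cell casts one hard vote.

    Each child cell votes for its KNN-majority parent cluster (probability
    ties broken by the lexicographically smaller cluster label); the one-hot
    votes are tabulated and size-normalized exactly like the soft votes.
    """
    probs = knn_vote(parent_features, parent_labels, child_features, k=k)
    arr = probs.to_numpy()
    # argmax with lexicographic tie-break: columns are already sorted
    winners = arr.argmax(axis=1)
    hard = np.zeros_like(arr)
    hard[np.arange(len(winners)), winners] = 1.0
    onehot = pd.DataFrame(hard, index=probs.index, columns=probs.columns)
    return tabulate_votes(
        onehot, child_labels, parent_features.groupby(
            pd.Series(parent_labels, index=parent_features.index)
        ).size(), mode=mode, k=k, **meta,
    )


def top_choices(
    row: pd.Series, dashed_threshold: float = 0.6
) -> tuple[str, str | None]:
    """(first choice, prominent second choice or None) for one vote row.

    The first choice is the argmax (ties to the lexicographically smaller
    parent label).  The second choice is reported only when its share
    exceeds ``dashed_threshold`` times the winning share and is positive.
    """
    row = row.sort_index()
    vals = row.to_numpy(dtype=float)
    first = int(np.argmax(vals))
    rest = vals.copy()
    rest[first] = -np.inf
    second = int(np.argmax(rest))
    first_label = row.index[first]
    if vals[second] > 0 and vals[second] > dashed_threshold * vals[first]:
        return first_label, row.index[second]
    return first_label, None


@dataclass
class StateTree:
    """Stage-layered tree: (stage, cluster) nodes, solid and dashed edges."""

    nodes: list[tuple[str, str]]
    solid_edges: dict[tuple[str, str], tuple[str, str]]
    dashed_edges: dict[tuple[str, str], tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "nodes": [list(n) for n in self.nodes],
            "solid_edges": [
                {"child": list(c), "parent": list(p)}
                for c, p in sorted(self.solid_edges.items())
            ],
            "dashed_edges": [
                {"child": list(c), "parent": list(p)}
                for c, p in sorted(self.dashed_edges.items())
            ],
        }

    def to_dot(self) -> str:
        lines = ["digraph state_tree {", "  rankdir=TB;"]
        for stage, cluster in self.nodes:
            lines.append(f'  "{stage}/{cluster}";')
        for (cs, cc), (ps, pc) in sorted(self.solid_edges.items()):
            lines.append(f'  "{ps}/{pc}" -> "{cs}/{cc}";')
        for (cs, cc), (ps, pc) in sorted(self.dashed_edges.items()):
            lines.append(f'  "{ps}/{pc}" -> "{cs}/{cc}" [style=dashed];')
        lines.append("}")
        return "\n".join(lines)


def build_tree(
    votes_by_transition: list[VoteMatrix], dashed_threshold: float = 0.6
) -> StateTree:
    """Assemble the state tree from per-transition vote matrices.

    Solid edge: argmax parent per child cluster (ties go to the
    lexicographically smaller parent id, logged).  Dashed edge: added iff
    the second-highest share exceeds ``dashed_threshold`` times the highest.
    """
    nodes: list[tuple[str, str]] = []
    solid: dict = {}
    dashed: dict = {}
    seen: set[tuple[str, str]] = set()
    for i, vm in enumerate(votes_by_transition):
        parent_stage = vm.parent_stage or f"stage{i + 1}"
        child_stage = vm.child_stage or f"stage{i + 2}"
        for stage, clusters in (
            (parent_stage, vm.table.columns),
            (child_stage, vm.table.index),
        ):
            for c in clusters:
                if (stage, c) not in seen:
                    seen.add((stage, c))
                    nodes.append((stage, c))
        for child, row in vm.table.iterrows():
            vals = row.sort_index()
            if (vals == vals.max()).sum() > 1:
                logger.info(
                    "build_tree: vote tie for child %r; choosing the "
                    "lexicographically smaller parent",
                    child,
                )
            first, second = top_choices(vals, dashed_threshold)
            solid[(child_stage, child)] = (parent_stage, first)
            if second is not None:
                dashed[(child_stage, child)] = (parent_stage, second)
    return StateTree(nodes=nodes, solid_edges=solid, dashed_edges=dashed)


def compare_tabulations(
    soft: VoteMatrix, hard: VoteMatrix, dashed_threshold: float = 0.6
) -> float:
    """Fraction of child clusters with identical first and second choices.

    "Second choice" means the prominent second choice (share above
    ``dashed_threshold`` x the winner, as drawn on the tree); both methods
    must agree on its presence and identity.
    """
    a, b = soft.table.sort_index(), hard.table.sort_index()
    if a.shape != b.shape or list(a.index) != list(b.index) or sorted(
        a.columns
    ) != sorted(b.columns):
        raise ValueError("vote matrices have mismatched shape or labels")
    agree = 0
    for child in a.index:
        if top_choices(a.loc[child], dashed_threshold) == top_choices(
            b.loc[child], dashed_threshold
        ):
            agree += 1
    return agree / len(a.index)
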