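"""End-to-end convenience pipelines over simulated datasets.

These wire the per-module operations together the way an analysis would:
voting runs within each tissue compartment, between consecutive stages,
using the union of planted marker genes of both stages as features.
"""

from __future__ import annotations

import pandas as pd

from . import statetree as st
from .datasets import SimulatedDataset
from .preprocess import normalize_log

__all__ = ["transition_votes", "vote_agreement", "lineage_recovery"]


def transition_votes(
    dataset: SimulatedDataset, k: int = 5
) -> list[tuple[st.VoteMatrix, st.VoteMatrix]]:
    """(soft, hard) vote-matrix pairs for every compartment and transition."""
    adata = normalize_log(dataset.adata)
    stages = list(adata.obs["stage"].cat.categories)
    out = []
    for comp in sorted(adata.obs["compartment"].cat.categories):
        sub = adata[adata.obs["compartment"] == comp]
        for parent_stage, child_stage in zip(stages, stages[1:]):
            ap = sub[sub.obs["stage"] == parent_stage]
            ac = sub[sub.obs["stage"] == child_stage]
            lp = ap.obs["cluster"].astype(str)
            lc = ac.obs["cluster"].astype(str)
            markers = {
                c: dataset.truth.marker_genes[c] for c in set(lp) | set(lc)
            }
            fp, fc, _ = st.build_feature_matrix(ap, ac, markers)
            probs = st.knn_vote(fp, lp, fc, k=k)
            soft = st.tabulate_votes(
                probs, lc, lp.value_counts(),
                parent_stage=parent_stage, child_stage=child_stage, k=k,
            )
            hard = st.hard_vote_confusion(
                fp, lp, fc, lc, k=k,
                parent_stage=parent_stage, child_stage=child_stage,
            )
            out.append((soft, hard))
    return out


def vote_agreement(
    dataset: SimulatedDataset, k: int = 5, dashed_threshold: float = 0.6
) -> tuple[int, int]:
    """(# child clusters with identical first+second choices, # clusters)."""
    agree = total = 0
    for soft, hard in transition_votes(dataset, k=k):
        frac = st.compare_tabulations(soft, hard, dashed_threshold)
        n = len(soft.table)
        agree += round(frac * n)
        total += n
    return agree, total


def lineage_recovery(
    dataset: SimulatedDataset, k: int = 5
) -> tuple[int, int]:
    """(# solid edges matching the planted lineage tree, # child clusters)."""
    ok = total = 0
    for soft, _ in transition_votes(dataset, k=k):
        tree = st.build_tree([soft])
        for (_, child), (_, parent) in tree.solid_edges.items():
            total += 1
            ok += dataset.truth.lineage_tree[child] == parent
    return ok, total
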