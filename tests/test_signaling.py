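"""Metagene, threshold-calling, and roadmap-inference tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from hypothesis.extra import numpy as hnp

import gutroadmap as gr
from gutroadmap.signaling import (
    PathwayGeneSets,
    SpatialLayout,
    Thresholds,
    call_senders_responders,
    compute_metagene,
    infer_edges,
    metagene_matrix,
    summarize_clusters,
    export_roadmap,
)
from gutroadmap.statetree import StateTree

from conftest import make_adata


class TestComputeMetagene:
    def test_single_gene_closed_form(self):
        counts = np.array([[0], [2], [4]])
        np.testing.assert_allclose(
            compute_metagene(counts, ["g0"], gene_names=["g0"]), [0, 0.5, 1.0]
        )

    def test_two_gene_worked_example(self):
        counts = np.array([[1, 10], [2, 0], [4, 10]])
        mg = compute_metagene(counts, ["A", "B"], gene_names=["A", "B"])
        np.testing.assert_allclose(mg, [0.625, 0.25, 1.0])

    def test_per_gene_scale_invariance(self):
        counts = np.array([[1, 10], [2, 0], [4, 10]], dtype=float)
        scaled = counts.copy()
        scaled[:, 1] *= 1000
        a = compute_metagene(counts, ["A", "B"], gene_names=["A", "B"])
        b = compute_metagene(scaled, ["A", "B"], gene_names=["A", "B"])
        np.testing.assert_allclose(a, b)

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, (10, 4))
        names = ["a", "b", "c", "d"]
        x = compute_metagene(counts, ["a", "c", "d"], gene_names=names)
        y = compute_metagene(counts, ["d", "a", "c"], gene_names=names)
        np.testing.assert_allclose(x, y)

    def test_all_zero_gene_is_ignored(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, (8, 3))
        counts[:, 2] = 0
        names = ["a", "b", "z"]
        with_zero = compute_metagene(counts, ["a", "b", "z"], gene_names=names)
        without = compute_metagene(counts, ["a", "b"], gene_names=names)
        np.testing.assert_allclose(with_zero, without)

    def test_empty_effective_set_warns_and_returns_zeros(self):
        counts = np.zeros((4, 2), dtype=int)
        with pytest.warns(UserWarning, match="no effective genes"):
            mg = compute_metagene(counts, ["g0"], gene_names=["g0", "g1"])
        np.testing.assert_array_equal(mg, 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        counts=hnp.arrays(
            np.int64, (6, 4), elements=st_.integers(min_value=0, max_value=50)
        )
    )
    def test_bounds_and_monotonicity(self, counts):
        names = list("abcd")
        mg = compute_metagene(counts, names, gene_names=names)
        assert (mg >= 0).all() and (mg <= 1 + 1e-12).all()
        if counts.max() > 0:
            assert mg.max() == pytest.approx(1.0)
        # raising one gene's count in one cell cannot lower the pre-scaling sum
        bumped = counts.copy()
        bumped[0, 0] += 5
        if counts[:, 0].max() > 0:
            sub, subb = counts.astype(float), bumped.astype(float)
            s = (sub / np.maximum(sub.max(axis=0), 1e-300)).sum(axis=1)
            sb = (subb / np.maximum(subb.max(axis=0), 1e-300)).sum(axis=1)
            assert sb[0] >= s[0] - 1e-9 or bumped[0, 0] == bumped[:, 0].max()


class TestSummarizeClusters:
    def make_metagenes(self, values, labels):
        df = pd.DataFrame({("BMP", "ligand"): values})
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["pathway", "role"])
        return df, pd.Series(labels, index=df.index)

    def test_identical_cluster_means_scale_to_zero(self):
        df, labels = self.make_metagenes([0.5, 0.5, 0.5, 0.5], list("AABB"))
        prof = summarize_clusters(df, labels)
        assert (prof["scaled"] == 0).all()

    def test_outlier_cluster_clipped_at_two(self):
        # 6 clusters: a single outlier's z-score is 5/sqrt(6) ~ 2.04 -> clipped
        vals = [0.01] * 10 + [1.0, 1.0]
        df, labels = self.make_metagenes(vals, list("AABBCCDDEEFF"))
        prof = summarize_clusters(df, labels)
        assert prof.loc[("F", "BMP", "ligand"), "scaled"] == 2.0

    def test_three_cluster_zscore_hand_oracle(self):
        df, labels = self.make_metagenes([0.1, 0.1, 0.2, 0.2, 0.6, 0.6], list("AABBCC"))
        prof = summarize_clusters(df, labels)
        means = np.array([0.1, 0.2, 0.6])
        z = (means - means.mean()) / means.std(ddof=1)
        got = [prof.loc[(c, "BMP", "ligand"), "scaled"] for c in "ABC"]
        np.testing.assert_allclose(got, z, rtol=1e-12)

    def test_pct_expressing(self):
        df, labels = self.make_metagenes([0.0, 0.4, 0.2, 0.2], list("AABB"))
        prof = summarize_clusters(df, labels)
        assert prof.loc[("A", "BMP", "ligand"), "pct_expressing"] == 0.5
        assert prof.loc[("B", "BMP", "ligand"), "pct_expressing"] == 1.0

    def test_single_cluster_rejected(self):
        df, labels = self.make_metagenes([0.1, 0.2], ["A", "A"])
        with pytest.raises(ValueError, match="raw means"):
            summarize_clusters(df, labels)


def profile_from_rows(rows):
    """rows: (cluster, pathway, role, scaled, pct)"""
    df = pd.DataFrame(
        rows, columns=["cluster", "pathway", "role", "scaled", "pct_expressing"]
    )
    df["mean"] = 0.5
    return df.set_index(["cluster", "pathway", "role"])


class TestCallerThresholds:
    def base_profile(self, lig_scaled, lig_pct, pathway="BMP"):
        rows = []
        for role, scaled, pct in (
            ("ligand", lig_scaled, lig_pct),
            ("receptor", 0.0, 1.0),
            ("response", 0.0, 1.0),
        ):
            rows.append(("X", pathway, role, scaled, pct))
        return profile_from_rows(rows)

    def test_boundary_minus_one_and_quarter_inclusive(self):
        prof = self.base_profile(-1.0, 0.25)
        flags = call_senders_responders(prof, Thresholds(ligand_mean_override={}))
        assert bool(flags.loc[("X", "BMP"), "can_send"])

    def test_notch_exception(self):
        notch = self.base_profile(-1.4, 0.3, pathway="Notch")
        flags = call_senders_responders(notch)
        assert bool(flags.loc[("X", "Notch"), "can_send"])
        other = self.base_profile(-1.4, 0.3, pathway="BMP")
        flags = call_senders_responders(other, Thresholds(ligand_mean_override={}))
        assert not bool(flags.loc[("X", "BMP"), "can_send"])

    def test_pct_below_quarter_blocks_all_flags(self):
        rows = [("X", "BMP", r, 2.0, 0.24) for r in ("ligand", "receptor", "response")]
        flags = call_senders_responders(
            profile_from_rows(rows), Thresholds(ligand_mean_override={})
        )
        assert not flags.loc[("X", "BMP")].any()

    def test_unknown_override_pathway_rejected(self):
        prof = self.base_profile(0.0, 1.0)
        with pytest.raises(ValueError, match="unknown pathway"):
            call_senders_responders(
                prof, Thresholds(ligand_mean_override={"Hippo": -1})
            )


class TestInferEdges:
    def layout(self):
        return SpatialLayout(
            layers={
                "DE": [f"de{i}" for i in range(10)],
                "SM": [f"sm{i}" for i in range(10)],
            },
            window=1,
        )

    def full_profile(self, spec):
        """spec: {(cluster, pathway, role): (scaled, pct)}; others low/off."""
        rows = []
        clusters = [f"de{i}" for i in range(10)] + [f"sm{i}" for i in range(10)]
        for c in clusters:
            for role in ("ligand", "receptor", "response"):
                scaled, pct = spec.get((c, "BMP", role), (-2.0, 0.0))
                rows.append((c, "BMP", role, scaled, pct))
        return profile_from_rows(rows)

    def test_autocrine_self_edge(self):
        spec = {
            ("de3", "BMP", "ligand"): (0.5, 1.0),
            ("de3", "BMP", "receptor"): (0.5, 1.0),
            ("de3", "BMP", "response"): (0.5, 1.0),
        }
        prof = self.full_profile(spec)
        flags = call_senders_responders(prof, Thresholds(ligand_mean_override={}))
        edges = infer_edges(flags, prof, self.layout())
        assert len(edges) == 1
        e = edges.iloc[0]
        assert (e["sender"], e["responder"], e["mode"]) == ("de3", "de3", "autocrine")
        assert e["strength"] == pytest.approx(1.0)
        assert e["strength_class"] == "strong"

    def test_response_gate_blocks_incoming(self):
        spec = {
            ("sm3", "BMP", "ligand"): (2.0, 1.0),
            ("de3", "BMP", "receptor"): (2.0, 1.0),
            # de3 response stays off
        }
        prof = self.full_profile(spec)
        flags = call_senders_responders(prof, Thresholds(ligand_mean_override={}))
        assert infer_edges(flags, prof, self.layout()).empty

    def test_adjacency_window_selects_apposed_cluster_only(self):
        spec = {
            ("sm3", "BMP", "ligand"): (1.0, 1.0),
            ("de3", "BMP", "receptor"): (0.5, 1.0),
            ("de3", "BMP", "response"): (0.5, 1.0),
            ("de9", "BMP", "receptor"): (0.5, 1.0),  # distant, also receptive
            ("de9", "BMP", "response"): (0.5, 1.0),
        }
        prof = self.full_profile(spec)
        flags = call_senders_responders(prof, Thresholds(ligand_mean_override={}))
        edges = infer_edges(flags, prof, self.layout())
        assert len(edges) == 1
        e = edges.iloc[0]
        assert (e["sender"], e["responder"], e["mode"]) == ("sm3", "de3", "paracrine")
        assert e["strength"] == pytest.approx(1.5)

    def test_strength_sum_rule(self):
        spec = {
            ("sm3", "BMP", "ligand"): (0.7, 1.0),
            ("de3", "BMP", "receptor"): (1.0, 1.0),
            ("de3", "BMP", "response"): (0.5, 1.0),
        }
        prof = self.full_profile(spec)
        flags = call_senders_responders(prof, Thresholds(ligand_mean_override={}))
        edges = infer_edges(flags, prof, self.layout())
        assert edges.iloc[0]["strength"] == pytest.approx(1.2)
        assert edges.iloc[0]["strength_class"] == "strong"

    def test_layout_rejects_duplicate_membership(self):
        with pytest.raises(ValueError, match="more than one layer"):
            SpatialLayout(layers={"DE": ["a"], "SM": ["a"]})


class TestExportRoadmap:
    def small_tree(self):
        return StateTree(
            nodes=[("s1", "de3"), ("s1", "sm3")],
            solid_edges={},
            dashed_edges={},
        )

    def test_letters_alphabetical_with_strong_flag(self):
        rows = []
        for p in ("Wnt", "BMP"):
            for role in ("ligand", "receptor", "response"):
                rows.append(("de3", p, role, 1.0, 1.0))
                rows.append(("sm3", p, role, -2.0, 0.0))
        prof = profile_from_rows(rows)
        flags = call_senders_responders(prof, Thresholds(ligand_mean_override={}))
        layout = SpatialLayout(layers={"DE": ["de3"], "SM": ["sm3"]})
        edges = infer_edges(flags, prof, layout)
        nodes, _ = export_roadmap(edges, prof, self.small_tree())
        row = nodes.set_index("cluster").loc["de3"]
        assert row["responding"] == "BMP,Wnt"
        assert row["strong"] == "BMP,Wnt"

    def test_empty_edges_valid(self):
        rows = [
            (c, "BMP", role, -2.0, 0.0)
            for c in ("de3", "sm3")
            for role in ("ligand", "receptor", "response")
        ]
        prof = profile_from_rows(rows)
        edges = infer_edges(
            call_senders_responders(prof, Thresholds(ligand_mean_override={})),
            prof,
            SpatialLayout(layers={"DE": ["de3"], "SM": ["sm3"]}),
        )
        nodes, etab = export_roadmap(edges, prof, self.small_tree())
        assert etab.empty and (nodes["responding"] == "").all()

    def test_cluster_missing_from_tree_warns(self):
        rows = [
            (c, "BMP", role, -2.0, 0.0)
            for c in ("de3", "sm3", "loose")
            for role in ("ligand", "receptor", "response")
        ]
        prof = profile_from_rows(rows)
        layout = SpatialLayout(layers={"DE": ["de3", "loose"], "SM": ["sm3"]})
        edges = infer_edges(
            call_senders_responders(prof, Thresholds(ligand_mean_override={})),
            prof,
            layout,
        )
        with pytest.warns(UserWarning, match="missing from the tree"):
            nodes, _ = export_roadmap(edges, prof, self.small_tree())
        assert nodes.set_index("cluster").loc["loose", "stage"] is None


def test_gene_sets_roles_must_be_disjoint():
    with pytest.raises(ValueError, match="both"):
        PathwayGeneSets({"BMP": {"ligand": ["a"], "receptor": ["a"]}})


def test_ligand_deletion_removes_exactly_those_edges(default_dataset):
    """Zeroing a sender's ligand genes removes its outgoing edges for that
    pathway and nothing else."""
    ds = default_dataset
    adata = ds.adata[ds.adata.obs["stage"] == "stage3"].copy()
    labels = adata.obs["cluster"].astype(str)
    clusters = sorted(labels.unique())
    layout = SpatialLayout.from_positions(
        {c: ds.truth.compartment[c] for c in clusters},
        {c: ds.truth.ap_position[c] for c in clusters},
    )

    def edge_set(a):
        mg = metagene_matrix(a, ds.pathways)
        prof = summarize_clusters(mg, labels)
        flags = call_senders_responders(prof)
        edges = infer_edges(flags, prof, layout)
        return set(zip(edges.pathway, edges.sender, edges.responder, edges["mode"]))

    before = edge_set(adata)
    sender = next(
        c for c in clusters if ds.truth.pathway_program[(c, "BMP", "ligand")] == "high"
    )
    mutated = adata.copy()
    X = mutated.X.tolil()
    cols = mutated.var_names.get_indexer(ds.pathways.genes("BMP", "ligand"))
    rows = np.flatnonzero((labels == sender).to_numpy())
    for r in rows:
        X[r, cols] = 0
    mutated.X = X.tocsr()
    after = edge_set(mutated)
    removed = before - after
    assert removed == {
        e for e in before if e[0] == "BMP" and e[1] == sender
    }
    assert after - before == set()
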