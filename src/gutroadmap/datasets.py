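"""Synthetic multi-stage, two-compartment scRNA-seq datasets with known truth.

The generator emulates the structure of a developing gut-tube dataset: three
developmental stages, an epithelial (DE-like) and a mesenchymal (SM-like)
compartment, a hierarchical cluster lineage across stages, a 1-D
anterior-posterior (A-P) positional axis with position-graded "Hox-like"
genes, and per-cluster ligand/receptor/response expression programs for six
signaling pathways.  Counts are drawn from a negative binomial (gamma-Poisson)
model, the standard noise model for UMI data.

Every downstream inference step (clustering, state-tree voting, pseudo-spatial
ordering, roadmap inference) can therefore be scored against a planted ground
truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PATHWAYS",
    "ROLES",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_ap_gradient",
]

PATHWAYS = ("BMP", "FGF", "HH", "Notch", "RA", "Wnt")
ROLES = ("ligand", "receptor", "response")

#: pathways whose planted responder cluster also expresses the ligand,
#: creating an autocrine loop on top of the paracrine edge
AUTOCRINE_PATHWAYS = frozenset({"Notch", "RA", "Wnt"})

_GENES_PER_ROLE = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the multi-stage simulation.

    ``clusters_per_stage`` counts clusters *per compartment*; a default run
    has 3+6+12 clusters in each of the DE-like and SM-like layers, so 42
    clusters and 6300 cells in total.
    """

    n_stages: int = 3
    clusters_per_stage: tuple[int, ...] = (3, 6, 12)
    cells_per_cluster: int = 150
    n_genes: int = 2000
    n_markers_per_cluster: int = 20
    marker_strength: float = 8.0
    child_perturbation: float = 1.0
    divergence_sd: float = 0.25
    nb_dispersion: float = 0.5
    library_size_mean: float = 3000.0
    n_gradient_genes: int = 10
    gradient_fold: float = 40.0
    n_compartment_markers: int = 20
    compartment_strength: float = 6.0
    pathway_off_mean: float = 0.02
    pathway_high_mean: float = 4.0
    position_jitter: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        cps = tuple(self.clusters_per_stage)
        if self.n_stages != len(cps):
            raise ValueError("n_stages must equal len(clusters_per_stage)")
        if any(c <= 0 for c in cps):
            raise ValueError("clusters_per_stage entries must be positive")
        if any(b < a for a, b in zip(cps, cps[1:])):
            raise ValueError("clusters_per_stage must be non-decreasing")
        if self.cells_per_cluster <= 0:
            raise ValueError("cells_per_cluster must be positive")
        for name in (
            "marker_strength",
            "nb_dispersion",
            "library_size_mean",
            "gradient_fold",
            "compartment_strength",
            "pathway_off_mean",
            "pathway_high_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.child_perturbation < 0:
            raise ValueError("child_perturbation must be >= 0")
        n_clusters = 2 * sum(cps)
        reserved = (
            self.n_markers_per_cluster * n_clusters
            + len(PATHWAYS) * len(ROLES) * _GENES_PER_ROLE
            + self.n_gradient_genes
            + 2 * self.n_compartment_markers
        )
        if reserved > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} is too small: {reserved} genes are "
                "needed for markers, pathway programs, gradient and "
                "compartment signatures"
            )

    @property
    def total_clusters(self) -> int:
        return 2 * sum(self.clusters_per_stage)


@dataclass
class GroundTruth:
    """Planted truth of a simulated dataset.

    ``pathway_program`` maps ``(cluster, pathway, role)`` to ``"off"`` or
    ``"high"``; ``mean_matrix`` holds the expected per-gene rates (arbitrary
    units, before library-size scaling) for every cluster.
    """

    lineage_tree: dict[str, str]
    ap_position: dict[str, float]
    compartment: dict[str, str]
    pathway_program: dict[tuple[str, str, str], str]
    marker_genes: dict[str, list[str]]
    gradient_genes: list[str]
    compartment_markers: dict[str, list[str]] = field(default_factory=dict)
    mean_matrix: pd.DataFrame | None = None

    def to_serializable(self) -> dict:
        d = {
            "lineage_tree": self.lineage_tree,
            "ap_position": self.ap_position,
            "compartment": self.compartment,
            "pathway_program": {
                "|".join(k): v for k, v in self.pathway_program.items()
            },
            "marker_genes": self.marker_genes,
            "gradient_genes": list(self.gradient_genes),
            "compartment_markers": self.compartment_markers,
        }
        return d

    @classmethod
    def from_serializable(cls, d: dict) -> "GroundTruth":
        program = {
            tuple(k.split("|")): v for k, v in d["pathway_program"].items()
        }
        return cls(
            lineage_tree=dict(d["lineage_tree"]),
            ap_position={k: float(v) for k, v in d["ap_position"].items()},
            compartment=dict(d["compartment"]),
            pathway_program=program,
            marker_genes={k: list(v) for k, v in d["marker_genes"].items()},
            gradient_genes=list(d["gradient_genes"]),
            compartment_markers={
                k: list(v) for k, v in d.get("compartment_markers", {}).items()
            },
        )


@dataclass
class SimulatedDataset:
    """Counts + annotation (AnnData), planted truth, and pathway gene sets."""

    adata: ad.AnnData
    truth: GroundTruth
    pathways: "PathwayGeneSets"  # noqa: F821 - forward ref, see signaling

    def __iter__(self):
        return iter((self.adata, self.truth, self.pathways))


def _stage_name(s: int) -> str:
    return f"stage{s + 1}"


def _cluster_name(stage: int, comp: str, idx: int) -> str:
    return f"st{stage + 1}_{comp}_c{idx:02d}"


def _sample_nb(rng, rates: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(rates)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, rates * dispersion)
    return rng.poisson(lam)


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Simulate a multi-stage two-compartment dataset with planted truth.

    Cluster mean construction: stage-1 clusters start from a shared lognormal
    baseline with compartment markers and their own marker genes up-shifted;
    a child cluster's mean equals its parent's mean multiplied per-gene by
    ``exp(N(0, (divergence_sd * child_perturbation)^2))`` with its own marker
    genes additionally up-shifted.  Pathway-program genes are pinned to fixed
    "off"/"high" rates inherited along the lineage, and position-graded genes
    are set once at stage 1 from the cluster's A-P position.

    Counts for each cell are negative binomial around the cluster's rate
    vector rescaled so that the expected library size is
    ``library_size_mean``.
    """
    from .signaling import PathwayGeneSets  # local import to avoid a cycle

    if config is None:
        config = SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genes = config.n_genes
    genes = np.array([f"g{i:04d}" for i in range(n_genes)])

    # --- partition the gene universe -------------------------------------
    order = rng.permutation(n_genes)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        block = order[cursor : cursor + n]
        cursor += n
        return block

    n_clusters = config.total_clusters
    marker_idx = take(config.n_markers_per_cluster * n_clusters).reshape(
        n_clusters, config.n_markers_per_cluster
    )
    pathway_idx: dict[tuple[str, str], np.ndarray] = {}
    for p in PATHWAYS:
        for role in ROLES:
            pathway_idx[(p, role)] = take(_GENES_PER_ROLE)
    gradient_idx = take(config.n_gradient_genes)
    comp_idx = {"DE": take(config.n_compartment_markers),
                "SM": take(config.n_compartment_markers)}

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    # --- cluster bookkeeping ---------------------------------------------
    cluster_names: list[str] = []
    cluster_stage: dict[str, int] = {}
    compartment: dict[str, str] = {}
    ap_position: dict[str, float] = {}
    lineage_tree: dict[str, str] = {}
    marker_genes: dict[str, list[str]] = {}
    program: dict[tuple[str, str, str], str] = {}
    means: dict[str, np.ndarray] = {}

    marker_cursor = 0
    for comp in ("DE", "SM"):
        prev: list[str] = []
        for s, k in enumerate(config.clusters_per_stage):
            current: list[str] = []
            for j in range(k):
                name = _cluster_name(s, comp, j)
                current.append(name)
                cluster_names.append(name)
                cluster_stage[name] = s
                compartment[name] = comp
                midx = marker_idx[marker_cursor]
                marker_cursor += 1
                marker_genes[name] = list(genes[midx])

                if s == 0:
                    pos = (j + 0.5) / k
                    mu = base.copy()
                    mu[comp_idx[comp]] *= config.compartment_strength
                    # stage-1 pathway program, assigned by A-P rank
                    for pi, p in enumerate(PATHWAYS):
                        home = pi % k
                        for role in ROLES:
                            level = "off"
                            if role == "ligand" and comp == "SM" and j == home:
                                level = "high"
                            if (
                                role == "ligand"
                                and comp == "DE"
                                and j == home
                                and p in AUTOCRINE_PATHWAYS
                            ):
                                level = "high"
                            if (
                                role in ("receptor", "response")
                                and comp == "DE"
                                and j == home
                            ):
                                level = "high"
                            program[(name, p, role)] = level
                    # position-graded "Hox-like" genes, half increasing and
                    # half decreasing along the axis
                    grad = np.empty(config.n_gradient_genes)
                    for gi in range(config.n_gradient_genes):
                        sign = 1.0 if gi % 2 == 0 else -1.0
                        grad[gi] = 0.5 * config.gradient_fold ** (sign * pos)
                    mu[gradient_idx] = grad
                else:
                    parent = prev[j * len(prev) // k]
                    lineage_tree[name] = parent
                    pos = float(
                        np.clip(
                            ap_position[parent]
                            + rng.normal(0.0, config.position_jitter),
                            0.0,
                            1.0,
                        )
                    )
                    noise = rng.normal(
                        0.0,
                        config.divergence_sd * config.child_perturbation,
                        n_genes,
                    )
                    if config.child_perturbation == 0:
                        noise[:] = 0.0
                    mu = means[parent] * np.exp(noise)
                    for p in PATHWAYS:
                        for role in ROLES:
                            program[(name, p, role)] = program[(parent, p, role)]

                ap_position[name] = pos
                mu[midx] *= config.marker_strength
                # pin pathway genes to their program levels
                for p in PATHWAYS:
                    for role in ROLES:
                        level = program[(name, p, role)]
                        rate = (
                            config.pathway_high_mean
                            if level == "high"
                            else config.pathway_off_mean
                        )
                        mu[pathway_idx[(p, role)]] = rate
                means[name] = mu
            prev = current

    # --- draw counts -------------------------------------------------------
    n_cells = len(cluster_names) * config.cells_per_cluster
    blocks = []
    obs_rows = []
    for name in cluster_names:
        mu = means[name]
        rates = mu / mu.sum() * config.library_size_mean
        block = _sample_nb(
            rng,
            np.broadcast_to(rates, (config.cells_per_cluster, n_genes)),
            config.nb_dispersion,
        )
        blocks.append(sp.csr_matrix(block.astype(np.int32)))
        obs_rows.append(
            pd.DataFrame(
                {
                    "stage": _stage_name(cluster_stage[name]),
                    "compartment": compartment[name],
                    "cluster": name,
                    "ap_position": ap_position[name],
                },
                index=range(config.cells_per_cluster),
            )
        )
    X = sp.vstack(blocks, format="csr")
    obs = pd.concat(obs_rows, ignore_index=True)
    obs.index = pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell")
    for col in ("stage", "compartment", "cluster"):
        obs[col] = obs[col].astype("category")

    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.uns["simulation"] = dataclasses.asdict(config)

    mean_matrix = pd.DataFrame(
        np.vstack([means[c] for c in cluster_names]),
        index=pd.Index(cluster_names, name="cluster"),
        columns=genes,
    )
    truth = GroundTruth(
        lineage_tree=lineage_tree,
        ap_position=ap_position,
        compartment=compartment,
        pathway_program=program,
        marker_genes=marker_genes,
        gradient_genes=list(genes[gradient_idx]),
        compartment_markers={c: list(genes[comp_idx[c]]) for c in comp_idx},
        mean_matrix=mean_matrix,
    )
    sets = {
        p: {role: list(genes[pathway_idx[(p, role)]]) for role in ROLES}
        for p in PATHWAYS
    }
    return SimulatedDataset(adata=adata, truth=truth, pathways=PathwayGeneSets(sets))


def simulate_ap_gradient(
    n_clusters: int = 12,
    cells_per_cluster: int = 100,
    n_genes: int = 300,
    n_gradient_genes: int = 50,
    n_markers_per_cluster: int = 10,
    marker_strength: float = 2.5,
    gradient_fold: float = 40.0,
    position_sd: float = 0.035,
    nb_dispersion: float = 0.5,
    library_size_mean: float = 3000.0,
    seed: int = 0,
) -> tuple[ad.AnnData, dict[str, float]]:
    """Simulate a single-stage, single-compartment A-P continuum.

    Unlike :func:`simulate_dataset`, which produces well-separated cluster
    blobs, this generator emulates a continuous positional field: every cell
    gets its own A-P coordinate (cluster center plus jitter) and a large
    panel of graded genes varies log-linearly along the axis, so that
    transcriptional distance tracks positional distance -- the regime in
    which diffusion-map flood pseudotime is a proxy of pseudo-space.

    Returns the counts (AnnData with per-cell ``cluster`` and ``position``)
    and the mapping cluster -> true A-P position.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:04d}" for i in range(n_genes)])
    order = rng.permutation(n_genes)
    gradient_idx = order[:n_gradient_genes]
    marker_idx = order[
        n_gradient_genes : n_gradient_genes + n_clusters * n_markers_per_cluster
    ].reshape(n_clusters, n_markers_per_cluster)

    base = rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)
    signs = np.where(np.arange(n_gradient_genes) % 2 == 0, 1.0, -1.0)
    offsets = rng.uniform(-0.3, 0.3, size=n_gradient_genes)

    centers = (np.arange(n_clusters) + 0.5) / n_clusters
    rows = []
    obs_rows = []
    for ci in range(n_clusters):
        pos = centers[ci] + rng.normal(0.0, position_sd, cells_per_cluster)
        pos = np.clip(pos, 0.0, 1.0)
        mu = np.broadcast_to(base, (cells_per_cluster, n_genes)).copy()
        mu[:, marker_idx[ci]] *= marker_strength
        grad = 0.5 * gradient_fold ** (signs * (pos[:, None] + offsets))
        mu[:, gradient_idx] = grad
        mu = mu / mu.sum(axis=1, keepdims=True) * library_size_mean
        rows.append(sp.csr_matrix(_sample_nb(rng, mu, nb_dispersion).astype(np.int32)))
        obs_rows.append(
            pd.DataFrame({"cluster": f"ap_c{ci:02d}", "position": pos})
        )
    X = sp.vstack(rows, format="csr")
    obs = pd.concat(obs_rows, ignore_index=True)
    obs.index = pd.Index(
        [f"cell{i:05d}" for i in range(X.shape[0])], name="cell"
    )
    obs["cluster"] = obs["cluster"].astype("category")
    adata = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    positions = {f"ap_c{ci:02d}": float(centers[ci]) for ci in range(n_clusters)}
    return adata, positions
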