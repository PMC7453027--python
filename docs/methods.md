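# Methods

This note documents the models and procedures implemented in `gutroadmap`,
the assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open.

## The setting

The package targets multi-stage scRNA-seq of a tissue with two apposed
compartments — an epithelial layer (DE-like, "definitive endoderm") and a
mesenchymal layer (SM-like, "splanchnic mesoderm") — organized along a 1-D
anterior–posterior (A-P) axis, profiled at consecutive developmental
stages. Three inferences are of interest: which earlier cell state each
later state descends from (the cell-state tree), where each cell state
sits along the axis (pseudo-space), and which clusters signal to which
through the major paracrine pathways (the signaling roadmap).

## Pathway metagenes and the signaling roadmap

A metagene collapses a role-specific gene set (ligands, receptors, or
context-independent response genes of a pathway) into a per-cell scalar:
per-gene max normalization over the full analysis universe, per-cell
summation, then division by the maximum summed value. The result lies in
[0, 1] and is invariant to per-gene scale, so highly and lowly expressed
pathway members contribute comparably. Two consequences matter in
practice: (i) the normalization universe must be the union of all cells
the profile will be compared across (both compartments together) — the
caller is responsible for passing that union; (ii) genes whose maximum
count is zero are dropped rather than producing 0/0.

Cluster profiles z-score the per-cluster mean metagene across clusters
(sample sd, ddof = 1) and clip to [−2, 2], the familiar dot-plot scale,
alongside the fraction of cells with metagene > 0 ("expressing"; the
threshold of strictly positive is our operationalization — any counts of
any member gene). Sender/receiver/responder calls are conjunctions:
scaled mean ≥ −1 **and** percent expressing ≥ 25%, both inclusive. Notch
ligands use a relaxed −1.5 mean threshold, compensating for their
uniformly low expression. The thresholds are applied to the scaled
averages — the −2..2 scale is the only one on which a −1 cutoff is
meaningful.

Edges are drawn per pathway for every cluster that both responds and can
receive: an autocrine self-edge if it also sends, and paracrine edges
from every spatially adjacent sender. Adjacency comes from a
`SpatialLayout`: per-layer A-P orderings with a rank window *w* (default
1) within a layer and across layers (apposition = equal rank ± *w*). The
layout can be supplied by the user or derived from known positions;
signaling is thereby restricted to short-range interactions. Edge
strength is the sum of the sender's scaled ligand metagene and the
responder's scaled response metagene; strength ≥ 1 is classed "strong".
Both the strength and the thresholds use scaled values consistently; raw
cluster means are retained in the profile for inspection.

## Cell-state trees by parent–child voting

Within a compartment, for each consecutive stage pair, a KNN classifier
(Euclidean distance, default k = 5, features = union of both stages'
cluster marker genes on log-normalized expression, no variance scaling)
gives each child cell a vote distribution over parent clusters (the
fraction of its k nearest parent cells per cluster; distance ties break
by parent cell index). Votes are averaged within each child cluster;
each parent column is then divided by that parent cluster's cell fraction
— without this, large parent clusters dominate by sheer neighbor
abundance — and rows are renormalized to 100%.

The top choice per child cluster becomes a solid tree edge; a second
choice is "prominent" (dashed) iff its share exceeds 60% of the winning
share. Argmax ties go to the lexicographically smaller parent label
(logged), which makes an exact two-way tie produce a solid edge to the
smaller label and a dashed edge to the other.

The hard-vote cross-check lets each child cell cast a single vote for its
KNN-majority parent cluster (probability ties again to the smaller
label), tabulated identically. Agreement between the soft and hard
tabulations is the fraction of child clusters whose first **and**
prominent-second choices coincide, counting "no prominent second" as a
choice in itself. Comparing raw second argmaxes instead would be
ill-defined for unanimous rows (every remaining share is zero) and would
give a single stray cell's vote the status of a "second choice"; the
prominence-gated definition compares exactly what the tree displays.

## Pseudo-spatial ordering by flood pseudotime

In a continuous field of tissue, transcriptional similarity tracks
spatial proximity, so a pseudotime rooted at one end of the field orders
cell populations along the axis — pseudo-space rather than developmental
time. The implementation: a Gaussian-kernel Markov matrix over cells
(adaptive bandwidth = distance to the k-th neighbor) is eigendecomposed;
the first 8 non-trivial diffusion components (eigenvalue-scaled) define
an embedding; a KNN graph (default k = 15) in that embedding carries
Gaussian edge weights renormalized into row-stochastic transition
probabilities. A disconnected graph is an error (component sizes
reported) — flood pseudotime is undefined across disconnected pieces.

Each flood simulation expands a visited set from the root cells: every
unvisited neighbor of the visited set is visited with probability equal
to its maximum transition probability from any visited neighbor; an
iteration that visits no one force-visits the most reachable frontier
cell, guaranteeing termination. Pseudotime is the mean first-visit
iteration over simulations (default 50; roots are 0). Clusters are
ordered by median pseudotime, ties broken by mean and then label — the
median is our reduction of the per-cluster pseudotime distribution to a
rank, chosen for robustness to stragglers.

On a deterministic chain (all transition probabilities 1) the procedure
reduces to breadth-first search and pseudotime equals hop distance
exactly; the Monte-Carlo standard error of the mean shrinks as 1/√n with
the number of simulations.

## QC, clustering, markers, TF codes

Count filtering keeps genes detected (count > 0) in ≥ 3 cells and then
cells with ≥ 100 detected genes; the gene filter runs first, a fixed and
documented order (the converse is equally defensible; the cascade can in
principle make a second pass remove more, so idempotence is a property of
realistic data rather than a theorem). Optional multiplet/mitochondrial
guards (`max_genes_per_cell`, `max_pct_mito`) default to off.
Normalization is counts-per-scale-factor (10,000) log1p. HVG selection
(default 1,500) uses the binned dispersion standardization (Seurat
flavor, via scanpy). Clustering scales the HVG matrix, takes 20 PCs, a
15-neighbor graph, and Leiden at resolution 1.0 (resolution is
configuration; small toy datasets need lower values than tissue-scale
data). Markers use a one-vs-rest two-sided Wilcoxon rank-sum test
(tie-corrected asymptotic) per gene, log2 fold changes on expm1-scale
means with pseudocount 1, and Benjamini–Hochberg adjustment within each
cluster. TF codes restrict the marker table to a user-supplied TF list
(e.g. the ~1,623 mouse TFs of AnimalTFDB) and keep the top 5 per cluster
by adjusted p then fold change, ties broken by gene name. Cell-cycle
regression and cross-stage anchor integration are deliberately not
implemented.

## Enrichment of perturbation gene lists

Cluster averages are min–max normalized per gene for heatmap use
(constant rows map to 0, logged). For enrichment, genes are ranked per
cluster by specificity — cluster mean minus the mean of all other
clusters — and scored with a weighted Kolmogorov–Smirnov running sum:
hits step up proportionally to |statistic|^weight (weight 1), misses step
down uniformly, ES = signed extremum, ES ∈ [−1, 1]. A set covering every
ranked gene has no misses; its ES is defined as 1 and flagged degenerate.

Significance uses gene-label permutations (default 1,000) — appropriate
because the input is an average matrix, not per-sample replicates — with
a +1 correction so p > 0 always. The p-value counts permutations whose
extremum is at least as extreme *in magnitude* as the observed ES;
direction is carried by the ES sign. This magnitude-based definition
keeps null p-values uniform and lets a maximally enriched set attain
exactly 1/(n_permutations + 1), which tail definitions conditioned on the
observed direction cannot do simultaneously. Within a cluster, the up
and down sets share one permutation seed, so identical sets give
identical results. BH adjustment runs across clusters per set.

## The synthetic-data generator

`simulate_dataset` emulates the study design the pipeline targets: 3
stages, 2 compartments, a per-compartment cluster ladder of 3 → 6 → 12
(so 42 clusters, 150 cells each, 6,300 cells total — `clusters_per_stage`
counts clusters per compartment, which keeps the DE/SM rank pairing
well-defined), 2,000 genes, and a planted ground truth for every
downstream inference:

- **Lineage**: stage-1 cluster means start from a shared lognormal
  baseline (σ = 1) with compartment markers (×6) and 20 own marker genes
  (×8) up-shifted; each child inherits its parent's mean times
  exp(N(0, (0.25 · child_perturbation)²)) per gene, plus its own ×8
  markers. Markers are disjoint across all clusters. At
  child_perturbation = 0 a child's mean equals its parent's away from its
  markers, exactly.
- **A-P axis**: stage-1 clusters are evenly spaced in [0, 1]; children
  inherit position ± N(0, 0.02). Ten "Hox-like" genes are set at stage 1
  as 0.5 · 40^(±position) (alternating directions) and inherited.
- **Signaling programs**: each pathway is assigned a home A-P rank at
  stage 1; the SM cluster at that rank gets high ligand, the apposed DE
  cluster high receptor + response (three pathways also get DE ligand,
  creating autocrine loops); descendants inherit the program, and program
  genes are pinned to fixed rates (off 0.02, high 4.0 — a 200× margin,
  comfortably above the 4× separability floor) rather than perturbed, so
  planted margins survive lineage noise.
- **Counts**: gamma–Poisson (negative binomial) with dispersion 0.5
  (Var = μ + 0.5 μ²) around the cluster's rate vector rescaled to an
  expected library size of 3,000 UMIs. Library size is constant across
  cells — a deliberate simplification that makes the NB variance law hold
  exactly within clusters; real data adds per-cell depth variation on
  top.

The default generator produces well-separated cluster blobs — the regime
clustering, voting, and roadmap recovery are tested in. That is *not*
the continuum regime pseudo-spatial ordering assumes (a KNN graph over
isolated blobs is disconnected), so a second generator,
`simulate_ap_gradient`, produces a single-stage continuum: every cell
gets its own position (cluster center ± 0.035), 50 graded genes vary
log-linearly along the axis with random offsets, and cluster markers are
mild (×2.5). One compartment, 12 clusters × 100 cells, 300 genes.

What passing tests on these data do and do not show: they establish that
each inference recovers exactly what was planted under its assumed regime
(separable programs, short-range signaling, a 1-D continuum, NB noise).
They do not establish robustness to doublets, ambient RNA, batch effects,
cell migration between lineages, per-cell depth variation, or programs
near the calling thresholds — none of which the generator simulates.

## Numerical and interface choices

- Determinism: every stochastic step takes a seed; fixed seeds give
  byte-identical simulations and reproducible clustering, floods, and
  permutation p-values. Diffusion-component signs are fixed by making
  each component's largest-magnitude entry positive.
- Degenerate inputs: zero-total cells are an error in normalization
  (impossible after QC); a single cluster is an error in profile scaling
  (z-scores undefined); an empty effective metagene gene list yields
  zeros with a warning, never an error; clusters with < 3 cells are
  skipped in marker testing with a warning.
- Vote matrices validate rows to 100% ± 1e−6; transition matrices to
  row sums 1 ± 1e−9.
- Files: MatrixMarket integer counts (genes × cells), TSV annotations,
  GMT pathway sets named `<PATHWAY>_ligand|_receptor|_response`, JSON
  ground truth and trees, Graphviz DOT for tree rendering. Writers
  refuse to overwrite without an explicit flag.

## Problem sizes

Multi-seed validations run on the default 6,300-cell simulation (20
replicates for tree recovery and soft/hard agreement, 10 for roadmap
recovery) and the 1,200-cell gradient simulation (10 replicates); flood
oracles use 10,000 simulations on 5-node toys. These sizes give
sampling error well below every margin tested while keeping the full
validation suite in the minutes range.

## Known limitations

- The spatial layout is 1-D with a fixed rank window; real organ
  geometry is 3-D and contact patterns are richer.
- Metagene thresholds are calibrated for dot-plot-scaled averages; raw
  thresholding would need different cutoffs.
- The voting tree links each child to exactly one parent per transition;
  convergent differentiation and migration violate that assumption by
  construction.
- Marker-feature voting depends on marker quality; with withheld ground
  truth, markers come from the Wilcoxon table and inherit its noise.
- GSEA here is the single-ranking, gene-permutation variant; it does not
  implement NES normalization across set sizes or sample-permutation
  nulls.
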