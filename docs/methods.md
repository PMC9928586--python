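# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter for reproducibility.

## Cluster-transition graph abstraction

**Model.** The cell-level shared-nearest-neighbour graph *G* (binary,
symmetric, zero diagonal) is summarized at cluster level as
*E* = (*GO*)ᵀ*O*, where *O* is the one-hot cluster assignment. *E[a, b]*
counts ordered adjacency entries from cells of cluster *b* to cells of
cluster *a*; each undirected edge contributes to both directions, so
within-cluster edges count twice on the diagonal and ΣΣ*E* equals twice the
number of undirected edges. Rows of *E* are normalized to transition
probabilities *P* (Hadamard division by the row totals *E·J*); rows of
isolated clusters become zero rows and are flagged rather than treated as
errors. Probabilities strictly below `p_min = 1e-4` are set to zero.
**No renormalization is applied after pruning**: pruning removes at most
a 10⁻⁴-mass per edge, and leaving the surviving values untouched keeps the
edge weights *w* = 1/*p* exactly the inverse of the reported probabilities.
Renormalization is available behind a flag for sensitivity analysis.

**Paths.** Lineage paths are minimum-total-weight directed paths found by
Dijkstra's algorithm on the k×k cluster graph. The implementation is a
small heap-based Dijkstra keyed on (distance, path): among equal-weight
paths the lexicographically smallest cluster-index sequence wins, making
results deterministic. k is the number of clusters (tens at most), so the
extra tuple comparisons are free. Unreachable targets are reported as
absent, not errors.

## Spot quality control

Spots with fewer than 300 UMIs or fewer than 100 detected genes are
removed ("fewer than" is strict: boundary values survive); genes detected
in fewer than 5 of the *surviving* spots are then removed. The order —
spots on the full matrix first, genes on the reduced matrix second — is a
single pass. A caveat: if a removed rare gene carried enough counts to keep
a spot above threshold, re-filtering the output could in principle remove
that spot, i.e. the single pass is not a fixed point in pathological cases;
in practice (and in all randomized tests) rare genes carry negligible mass
and the filter is idempotent. Mitochondrial/ribosomal/non-coding removal is
an explicit user-supplied exclusion list applied before any counting, not a
hard-coded annotation lookup.

## Marker statistics

δpct for a (gene, cluster) pair is the fraction of cluster cells with raw
count > 0 minus the same fraction outside the cluster; it depends only on
the zero pattern, so it is invariant to monotone transforms of nonzero
counts. Fold changes are computed on counts normalized to 10,000 per cell
and log2(x+1)-transformed; the fold-change statistic itself is
ln(mean_in + ε) − ln(mean_out + ε) with ε = 10⁻⁹. The log base for the
0.1 acceptance threshold is a genuine ambiguity in common usage; the
natural-log (Seurat-era) convention is the default and base 2 is a flag.
Acceptance thresholds (pct_in ≥ 0.25, log-FC ≥ 0.1, δpct ≥ 0.10, adjusted
p < 0.001 when p-values are supplied) are inclusive except the p-value.
The interactome expression filter keeps genes whose per-cluster mean
log2-normalized expression is *strictly* above 0.3 in some cluster.

## Panel curation

**Typer.** Cells are typed by maximum a posteriori under independent
negative binomials: assigned type = argmax over types of
Σ_g log NB(count_g | mean[g, t], size) + log prior (uniform by default).
Simulated cells have known read-to-cell assignment, so a segmentation-aware
typer would add machinery without changing the decision rule; this is the
minimal probabilistic model for the task. Mean-zero entries are floored at
10⁻⁶ so log-likelihoods stay finite; ties break lexicographically on the
sorted type ids. The typer is exposed as a scikit-learn-style estimator
(`fit`/`predict`/`predict_proba`, `classes_`, `mean_expr_`) and can
alternatively be built directly from reference profiles.

**Contribution metric.** No quantitative definition of a gene's
"contribution" to correct typing is established in common use, so it is
defined here as the paired leave-one-gene-out accuracy drop:
contribution[g, t] = accuracy_t(panel) − accuracy_t(panel \ {g}), computed
on the same simulated cells and averaged over `n_rep = 5` replicate fields
to damp Monte-Carlo noise. Pairing matters: a gene with identical means in
all types changes no cell's likelihood ranking, so its contribution is
essentially zero rather than zero-plus-simulation-noise.

**Loop.** Each iteration simulates `n_rep` fields of `n_cells = 3000`
cells on the current panel, computes contributions, keeps the union over
types of the top `keep_per_type = 5` contributors (ties lexicographic) and
measures the reduced panel's per-type accuracy on the same cells. The loop
stops when every type reaches `accuracy_target = 0.95` or after
`max_iters`; "predicts all types correctly" is read as a per-type accuracy
floor because exact 100 % is attainable only in noiseless regimes. If the
target is never reached the best panel seen is returned with
`converged=False`.

**Study conditions.** The planted-profile generator defaults to 3 types ×
5 markers at 8-fold enrichment over a base mean of 0.3 molecules per cell
per gene (NB size 2), plus 20 uninformative genes. The low absolute means
are deliberate: targeted in-situ chemistry yields fractions of a molecule
to a few molecules per cell per gene, and this regime keeps single-marker
removal measurable instead of saturating accuracy at 1.

## Co-localization neighbourhoods

Pearson correlation of per-spot cell-type fractions is computed across all
pooled spots (per-section standardization is a flag; pooling is the
default). Edges require *r* strictly greater than `r_min = 0.04`;
neighbourhoods are the connected components of the thresholded graph.
Components were chosen over community detection because the thresholded
graph is expected to separate into a small number of visually distinct
groups; an optional Leiden step is available for graphs that threshold
into one giant component. Type exclusion and merging (e.g. pooling
neuronal subtypes, dropping immune types) are explicit options.

## Airway zonation

**Binning.** Square-lattice bins with 20 µm "radius" (40 µm pitch,
nearest-center assignment = coordinate rounding) are the default for
ISS-scale data; hexagonal binning is available. Binning conserves total
read counts exactly.

**Airway detection.** ISS mode: bins with more than 3 EPCAM molecules.
ST (spot) mode: entities whose summed counts over a user-supplied
epithelial marker set exceed 8 UMIs (the marker set is a user input; no
canonical top-10 list ships with the package).

**Radial axis.** Center-to-center Euclidean distance to the nearest airway
bin, in µm; airway bins are 0 and distances above 140 µm are flagged
excluded.

**PD axis.** Spot mode: each marker gene is min–max scaled across airway
spots; with p and d the mean scaled proximal (SOX2, SCGB3A2) and distal
(ETV5, TPPP3) aggregates, the score is (d − p)/(d + p), and 0 when
d + p = 0. This form was chosen because it is bounded, symmetric, and hits
exactly −1/+1 on pure-proximal/pure-distal spots — the printed endpoint
convention; a plain scaled difference is available behind a flag. ISS
mode: airway-bin composition vectors (per-bin gene fractions) are reduced
to one dimension; the default is the first principal component because it
is deterministic, with UMAP dimension 1 (the stochastic original) behind
`method="umap"`. The axis is oriented so the proximal-marker aggregate
correlates negatively with the score, then min–max rescaled to [−1, 1].
Equivalence of the two embeddings is a rank-correlation check, not an
identity. Non-airway entities inherit the PD score of their nearest airway
bin (ties to the lowest bin index).

**Density maps.** PD is rounded to a 0.1 grid (no canonical grid exists;
one decimal is the default and configurable) and radial to the bin pitch;
ISS mode histograms labeled entities with optional Gaussian smoothing, ST
mode averages per-cluster fractions over entities sharing a grid cell.
Each cluster's grid is normalized to maximum 1, so maps show relative
occupancy, not absolute density.

## Hexagonal-bin NE analysis

Pointy-top hexagons with 7 µm circumradius are the default ("radius" and
"width" are both in circulation for this bin size; width and flat-top
interpretations are selectable). Reads are assigned by exact axial cube
rounding — verified against a point-in-polygon oracle — so counts are
conserved. Retained bins must pass SOX2 > 3 AND EPCAM > 3, and
(Σ NE-genes ≥ 12 OR ASCL1 > 10); the NE gene set defaults to ARX, NKX2-2,
GHRL, ACSL1, CALCA, GRP, RFX6, CFC1, PCSK1, ASCL1. Before Leiden
clustering (resolution 0.1, seeded, k = 15 kNN graph) bin vectors are
library-size normalized to the median bin total and log1p-transformed;
whether to normalize at all is a genuine open choice and the normalization
is flagged so it can be disabled by clustering the raw counts through the
library surface directly. Gene–gene Pearson correlations are computed
across retained bins, with constant genes reported missing.

## Synthetic data: what it does and does not emulate

All generators are pure functions of (parameters, seed) and emit their
ground truth alongside the data.

* `simulate_cell_dataset` draws counts NB(mean, size) per (cell type,
  gene) with a shared size parameter (default 2). The phrase "negative
  binomial with r the mean expression" is read as mean-parametrization;
  the size is a separate knob because sizing by the mean would be unusual.
* `simulate_snn_graph` places independent Bernoulli edges per cluster
  pair. Real SNN graphs have degree structure and transitivity that
  Bernoulli graphs lack; the planted quantity (relative inter-cluster
  connectivity) is what downstream abstraction consumes.
* `simulate_spot_fractions` gives each spot flat-Dirichlet mass over one
  planted block plus truncated-normal noise (σ = 0.02) elsewhere, rows
  renormalized. Real deconvolution output has per-section composition
  shifts and correlated errors that are not modeled.
* `simulate_airway_tissue` uses a straight 1000 µm airway path with ~300
  epithelial cells (EPCAM at 40 % of the per-cell read budget; proximal
  markers decaying linearly along arc length, distal rising), mesenchymal
  types at planted (radial, PD) Gaussian positions (defaults: an
  airway-fibroblast-like type at 20 ± 4 µm radial / PD −0.8, a smooth-
  muscle-like type at 40 µm / −0.4, an adventitial-like type at 90 µm /
  0.3), Poisson reads (the NB limit appropriate for molecule tables) at 50
  reads per cell, and 2 µm isotropic read scatter. True PD is arc length
  rescaled to [−1, 1]. Branching geometry, curved airways, segmentation
  errors and optical crowding are not emulated — passing recovery tests
  shows the coordinate pipeline is correct on clean geometry, not that it
  is robust to those artifacts.

## Problem sizes

Randomized oracles use 100–200 instances of ≤ 30 cells / ≤ 5 clusters for
the graph identities, 1,000 points for geometric oracles, 2,000 spots for
co-localization, 3,000 cells per panel-curation iteration and ~24,000
reads per synthetic tissue; recovery claims aggregate 10 generator seeds.
These sizes give stable Monte-Carlo margins for every threshold tested
while keeping the full suite and the acceptance script in the
tens-of-seconds range.

## Known limitations

* The graph abstraction assumes an unweighted, symmetric SNN graph; fuzzy
  or weighted neighbour graphs must be binarized first.
* The NB typer ignores spatial position by construction; on simulated
  uniform fields this is exact (typing is permutation-invariant in
  position), on real tissue a segmentation-aware typer could do better.
* PD scores are relative per section: min–max scaling maps each section's
  observed extremes to ±1, so scores are not comparable across sections
  without joint scaling.
* The ST airway-marker set and the density-map smoothing bandwidth are
  user inputs; no defaults are claimed to be canonical.
* `qc_filter_spots` is single-pass (see above) and not guaranteed
  idempotent on adversarial inputs.
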