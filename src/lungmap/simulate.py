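"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its parameters and seed and returns the
planted truth alongside the data, so downstream recovery can be scored without
any external dataset:

* :func:`simulate_cell_dataset` — per-cluster negative-binomial cell x gene
  counts (the same sampling model used for panel-selection fields);
* :func:`simulate_snn_graph` — binary SNN-like cell graphs with planted
  inter-cluster connectivity;
* :func:`simulate_spot_fractions` — spot x cell-type fraction matrices with
  planted co-occurrence blocks;
* :func:`simulate_airway_tissue` — a molecule-level read table over a 1D
  airway with a planted proximal--distal expression gradient and mesenchymal
  cells at known (radial, PD) positions.

The negative binomial is parametrized by (mean, size): ``size`` is the shared
dispersion parameter (variance = mean + mean^2 / size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PROXIMAL_GENES = ("SOX2", "SCGB3A2")
DISTAL_GENES = ("ETV5", "TPPP3")


@dataclass
class ExpressionProfiles:
    """Mean expression per gene (rows) and cell type (columns), plus a shared
    negative-binomial size (dispersion) parameter."""

    mean_expr: np.ndarray  # (n_genes, n_types), finite, >= 0
    gene_ids: np.ndarray
    type_ids: np.ndarray
    dispersion: float = 2.0

    def __post_init__(self) -> None:
        self.mean_expr = np.asarray(self.mean_expr, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.type_ids = np.asarray(self.type_ids, dtype=object)
        if self.mean_expr.shape != (len(self.gene_ids), len(self.type_ids)):
            raise ValueError("mean_expr shape does not match gene/type ids")
        if not np.isfinite(self.mean_expr).all() or (self.mean_expr < 0).any():
            raise ValueError("means must be finite and non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def restrict(self, genes: Sequence[str]) -> "ExpressionProfiles":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in profiles: {missing}")
        rows = [idx[g] for g in genes]
        return ExpressionProfiles(self.mean_expr[rows], np.asarray(list(genes), dtype=object),
                                  self.type_ids, self.dispersion)


@dataclass
class GroundTruth:
    """Planted truth emitted next to every simulated dataset."""

    labels: np.ndarray | None = None  # per-cell type labels
    marker_map: dict = field(default_factory=dict)  # gene -> type
    cells: pd.DataFrame | None = None  # per-cell x, y, radial, pd, type
    blocks: list = field(default_factory=list)  # planted co-occurrence blocks


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """NB(mean, size) samples; mean-0 entries are exactly zero."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def planted_marker_profiles(
    n_types: int = 3,
    markers_per_type: int = 5,
    n_noise_genes: int = 20,
    base_mean: float = 0.3,
    fold: float = 8.0,
    dispersion: float = 2.0,
) -> tuple[ExpressionProfiles, GroundTruth]:
    """Profiles with ``markers_per_type`` planted ``fold``-times-enriched
    markers per cell type plus type-uninformative noise genes.

    The default means emulate targeted in-situ panels, where individual genes
    yield low per-cell molecule counts (well below one to a few molecules).
    """
    type_ids = [f"type{t}" for t in range(n_types)]
    gene_ids, marker_map = [], {}
    rows = []
    for t, tid in enumerate(type_ids):
        for m in range(markers_per_type):
            g = f"mk_{tid}_{m}"
            gene_ids.append(g)
            marker_map[g] = tid
            row = np.full(n_types, base_mean)
            row[t] = base_mean * fold
            rows.append(row)
    for j in range(n_noise_genes):
        gene_ids.append(f"noise_{j}")
        rows.append(np.full(n_types, base_mean))
    profiles = ExpressionProfiles(np.array(rows), np.array(gene_ids, dtype=object),
                                  np.array(type_ids, dtype=object), dispersion)
    return profiles, GroundTruth(marker_map=marker_map)


def simulate_cell_dataset(
    n_cells: int,
    profiles: ExpressionProfiles,
    type_props: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw cell types from ``type_props`` and cell x gene counts from
    NB(mean_expr[g, type], dispersion). Returns (counts, labels)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    k = len(profiles.type_ids)
    if type_props is None:
        type_props = np.full(k, 1.0 / k)
    type_props = np.asarray(type_props, dtype=float)
    if type_props.shape != (k,) or not np.isclose(type_props.sum(), 1.0):
        raise ValueError("type_props must be a length-k vector summing to 1")
    rng = np.random.default_rng(seed)
    type_idx = rng.choice(k, size=n_cells, p=type_props)
    counts = _nb_sample(rng, profiles.mean_expr.T[type_idx], profiles.dispersion)
    return counts, profiles.type_ids[type_idx]


def simulate_snn_graph(
    labels: Sequence,
    inter_cluster_edge_prob: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Undirected simple graph with edge probability given per cluster pair.

    ``inter_cluster_edge_prob`` is k x k symmetric with entries in [0, 1],
    indexed by the sorted unique labels. Returns a binary adjacency matrix.
    """
    labels = np.asarray(labels)
    prob = np.asarray(inter_cluster_edge_prob, dtype=float)
    if prob.ndim != 2 or prob.shape[0] != prob.shape[1]:
        raise ValueError("probability matrix must be square")
    if not np.allclose(prob, prob.T):
        raise ValueError("probability matrix must be symmetric")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    clusters = np.unique(labels)
    if len(clusters) != prob.shape[0]:
        raise ValueError("probability matrix size does not match cluster count")
    idx = np.searchsorted(clusters, labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    p_cell = prob[np.ix_(idx, idx)]
    upper = np.triu(rng.random((n, n)) < p_cell, k=1)
    adj = (upper | upper.T).astype(np.int8)
    return adj


def simulate_spot_fractions(
    n_spots: int,
    blocks: Sequence[Sequence[str]],
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Spot x cell-type fractions with planted co-occurrence blocks.

    Each spot is assigned to one block; types inside the block receive a
    flat-Dirichlet share of the spot, the rest receive truncated-normal noise.
    Rows are renormalized to sum to one.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    blocks = [list(b) for b in blocks]
    if any(len(b) == 0 for b in blocks):
        raise ValueError("empty block")
    type_ids = sorted({t for b in blocks for t in b})
    col = {t: j for j, t in enumerate(type_ids)}
    rng = np.random.default_rng(seed)
    frac = np.abs(rng.normal(0.0, noise_sd, size=(n_spots, len(type_ids))))
    which = rng.integers(len(blocks), size=n_spots)
    for b, members in enumerate(blocks):
        spots = np.flatnonzero(which == b)
        mass = rng.dirichlet(np.ones(len(members)), size=len(spots))
        frac[np.ix_(spots, [col[t] for t in members])] += mass
    frac /= frac.sum(axis=1, keepdims=True)
    df = pd.DataFrame(frac, columns=type_ids,
                      index=[f"spot{i}" for i in range(n_spots)])
    return df, GroundTruth(blocks=blocks, labels=which)


def simulate_airway_tissue(
    trunk_length: float = 1000.0,
    n_epith_cells: int = 300,
    mesench_placement: Mapping[str, dict] | None = None,
    proximal_genes: Sequence[str] = PROXIMAL_GENES,
    distal_genes: Sequence[str] = DISTAL_GENES,
    reads_per_cell: float = 50.0,
    epcam_fraction: float = 0.4,
    epith_half_width: float = 8.0,
    read_jitter: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Molecule-level reads over a straight airway with a planted PD gradient.

    Epithelial cells sit along a 1D airway path of length ``trunk_length`` um;
    their proximal-marker read rate decreases linearly with arc length while
    the distal-marker rate increases, and every epithelial cell expresses
    EPCAM. True PD is arc length rescaled to [-1, 1]. Mesenchymal cell types
    are placed at planted (radial um, PD) positions given by
    ``mesench_placement``: a mapping ``type -> {"n": int, "radial": (mean, sd),
    "pd": (mean, sd), "genes": [markers]}``. Reads are Poisson per cell and
    gene, scattered with isotropic ``read_jitter``.

    Returns the read table (columns x, y, gene) and a :class:`GroundTruth`
    whose ``cells`` frame stores each cell's position, true radial distance
    and true PD score.
    """
    if reads_per_cell <= 0:
        raise ValueError("reads_per_cell must be positive")
    if set(proximal_genes) & set(distal_genes):
        raise ValueError("proximal and distal marker sets must be disjoint")
    if mesench_placement is None:
        mesench_placement = {
            "AF": {"n": 60, "radial": (20.0, 4.0), "pd": (-0.8, 0.05),
                   "genes": ["ASPN", "TNC"]},
            "ASM": {"n": 60, "radial": (40.0, 6.0), "pd": (-0.4, 0.1),
                    "genes": ["MYH11", "DACH2"]},
            "AdvF": {"n": 60, "radial": (90.0, 10.0), "pd": (0.3, 0.2),
                     "genes": ["SERPINF1", "SFRP2"]},
        }
    rng = np.random.default_rng(seed)
    marker_frac = 1.0 - epcam_fraction

    cells = []
    # epithelial cells: evenly spaced arc positions with jitter
    s = np.sort(rng.uniform(0.0, trunk_length, size=n_epith_cells))
    offsets = rng.uniform(-epith_half_width, epith_half_width, size=n_epith_cells)
    for i in range(n_epith_cells):
        cells.append({"cell_id": f"epi{i}", "type": "epithelial",
                      "x": s[i], "y": offsets[i],
                      "radial": 0.0, "pd": 2.0 * s[i] / trunk_length - 1.0})
    for tname, spec in mesench_placement.items():
        n_t = int(spec["n"])
        r_mu, r_sd = spec["radial"]
        pd_mu, pd_sd = spec["pd"]
        radial = np.clip(rng.normal(r_mu, r_sd, size=n_t), 0.0, None)
        pd_true = np.clip(rng.normal(pd_mu, pd_sd, size=n_t), -1.0, 1.0)
        side = rng.choice([-1.0, 1.0], size=n_t)
        for i in range(n_t):
            cells.append({"cell_id": f"{tname}{i}", "type": tname,
                          "x": (pd_true[i] + 1.0) / 2.0 * trunk_length,
                          "y": side[i] * (epith_half_width + radial[i]),
                          "radial": radial[i], "pd": pd_true[i]})
    truth = pd.DataFrame(cells)

    # per-cell gene rates
    records_x, records_y, records_g = [], [], []

    def _emit(cell, gene, rate):
        k = rng.poisson(rate)
        if k:
            records_x.append(cell["x"] + rng.normal(0.0, read_jitter, size=k))
            records_y.append(cell["y"] + rng.normal(0.0, read_jitter, size=k))
            records_g.extend([gene] * k)

    for cell in cells:
        if cell["type"] == "epithelial":
            u = (cell["pd"] + 1.0) / 2.0  # 0 proximal, 1 distal
            _emit(cell, "EPCAM", epcam_fraction * reads_per_cell)
            for g in proximal_genes:
                _emit(cell, g, marker_frac * reads_per_cell * (1.0 - u) / len(proximal_genes))
            for g in distal_genes:
                _emit(cell, g, marker_frac * reads_per_cell * u / len(distal_genes))
        else:
            genes = mesench_placement[cell["type"]]["genes"]
            for g in genes:
                _emit(cell, g, reads_per_cell / len(genes))

    reads = pd.DataFrame({
        "x": np.concatenate(records_x) if records_x else np.array([]),
        "y": np.concatenate(records_y) if records_y else np.array([]),
        "gene": records_g,
    })
    return reads, GroundTruth(labels=truth["type"].to_numpy(), cells=truth)
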