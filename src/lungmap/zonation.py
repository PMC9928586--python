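"""Two-axis airway zonation: radial distance and proximal--distal score.

Molecule-level (ISS-like) reads are binned on a square or hexagonal lattice;
bins rich in an airway marker (EPCAM > 3 by default) define the airway. Every
bin then gets a radial coordinate (Euclidean distance to the nearest airway
bin, bins beyond 140 um excluded) and a proximal--distal (PD) score in
[-1, 1]: airway bins are scored directly -- from marker expression for
spot-level (ST-like) data, or from a 1D embedding of airway-bin expression
for ISS data -- and every non-airway bin inherits the score of its nearest
airway bin. Per-cluster occupancy along (PD, radial) is summarized as
density maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .hexbin import hex_assign, hex_center
from .simulate import DISTAL_GENES, PROXIMAL_GENES


@dataclass
class BinGrid:
    """Per-bin gene counts on a square or hexagonal lattice."""

    geometry: str  # "square" | "hex"
    radius: float  # um; half bin pitch for square, circumradius for hex
    centers: np.ndarray  # (n_bins, 2)
    counts: np.ndarray  # (n_bins, n_genes)
    gene_ids: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def gene_counts(self, gene: str) -> np.ndarray:
        idx = np.flatnonzero(self.gene_ids == gene)
        if len(idx) == 0:
            raise KeyError(f"gene {gene!r} not in grid")
        return self.counts[:, idx[0]]


def bin_reads(reads: pd.DataFrame, geometry: str = "square",
              radius: float = 20.0) -> BinGrid:
    """Assign each read to the nearest bin center on the chosen lattice.

    Square lattice: centers every ``2 * radius`` um (nearest-center assignment
    is coordinate rounding). Hex lattice: pointy-top hexagons of circumradius
    ``radius``. Total counts are conserved exactly.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(reads) == 0:
        raise ValueError("empty read table")
    x = reads["x"].to_numpy(dtype=float)
    y = reads["y"].to_numpy(dtype=float)
    if geometry == "square":
        pitch = 2.0 * radius
        keys_f = np.stack([np.round(x / pitch), np.round(y / pitch)], axis=1)
        keys_all = keys_f.astype(np.int64)
        center_of = lambda k: k.astype(float) * pitch
    elif geometry == "hex":
        keys_all = hex_assign(x, y, radius)
        center_of = lambda k: hex_center(k, radius)
    else:
        raise ValueError("geometry must be 'square' or 'hex'")
    genes = np.array(sorted(reads["gene"].unique()), dtype=object)
    g_idx = {g: j for j, g in enumerate(genes)}
    keys, inverse = np.unique(keys_all, axis=0, return_inverse=True)
    counts = np.zeros((len(keys), len(genes)), dtype=np.int64)
    cols = reads["gene"].map(g_idx).to_numpy()
    np.add.at(counts, (inverse, cols), 1)
    return BinGrid(geometry=geometry, radius=radius, centers=center_of(keys),
                   counts=counts, gene_ids=genes)


def airway_bins(grid: BinGrid, gene: str | Sequence[str] = "EPCAM",
                min_count: int = 3) -> np.ndarray:
    """Airway mask: bins whose count of ``gene`` -- or summed counts of a gene
    set, the spot-level convention -- strictly exceeds ``min_count``."""
    if isinstance(gene, str):
        total = grid.gene_counts(gene)
    else:
        total = sum(grid.gene_counts(g) for g in gene)
    return total > min_count


def radial_axis(grid: BinGrid, mask: np.ndarray,
                max_radial: float = 140.0) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each bin center to the nearest airway bin center.

    Returns (radial, excluded): airway bins have radial 0; bins farther than
    ``max_radial`` um are flagged excluded.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty airway mask")
    d = cdist(grid.centers, grid.centers[mask])
    radial = d.min(axis=1)
    radial[mask] = 0.0
    return radial, radial > max_radial


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v, dtype=float)
    return (v - lo) / (hi - lo)


def pd_score_st(grid: BinGrid, airway_mask: np.ndarray,
                proximal_genes: Sequence[str] = PROXIMAL_GENES,
                distal_genes: Sequence[str] = DISTAL_GENES,
                method: str = "ratio") -> np.ndarray:
    """Marker-based PD score for airway spots/bins, in [-1, 1].

    Each marker gene is min--max scaled across airway entries; p and d are the
    mean scaled proximal and distal aggregates. ``method="ratio"`` scores
    (d - p) / (d + p) (0 where d + p = 0), hitting exactly -1 / +1 for
    pure-proximal / pure-distal spots; ``method="difference"`` scores d - p.
    Non-airway entries are NaN (see :func:`propagate_pd`).
    """
    prox = [g for g in proximal_genes if g in grid.gene_ids]
    dist = [g for g in distal_genes if g in grid.gene_ids]
    if set(proximal_genes) & set(distal_genes):
        raise ValueError("marker sets must be disjoint")
    if not prox and not dist:
        raise ValueError("no proximal or distal marker genes in panel")
    mask = np.asarray(airway_mask, dtype=bool)
    def aggregate(genes):
        if not genes:
            return np.zeros(int(mask.sum()))
        return np.mean([_minmax(grid.gene_counts(g)[mask].astype(float))
                        for g in genes], axis=0)
    p = aggregate(prox)
    d = aggregate(dist)
    if method == "ratio":
        tot = d + p
        score = np.where(tot > 0, (d - p) / np.where(tot > 0, tot, 1.0), 0.0)
    elif method == "difference":
        score = d - p
    else:
        raise ValueError("method must be 'ratio' or 'difference'")
    out = np.full(grid.n_bins, np.nan)
    out[mask] = score
    return out


def pd_embedding_iss(grid: BinGrid, airway_mask: np.ndarray,
                     method: str = "pca",
                     proximal_genes: Sequence[str] = PROXIMAL_GENES,
                     seed: int = 0) -> np.ndarray:
    """Expression-embedding PD score for airway bins, in [-1, 1].

    The airway bins' composition vectors (per-bin gene fractions) are reduced
    to one dimension -- the first principal component by default
    (deterministic), or UMAP dimension 1 with ``method="umap"``. The axis is
    oriented so the proximal-marker aggregate correlates negatively with the
    score, then min--max rescaled to [-1, 1]. Non-airway bins are NaN.
    """
    mask = np.asarray(airway_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 airway bins")
    x = grid.counts[mask].astype(float)
    totals = x.sum(axis=1, keepdims=True)
    x = x / np.where(totals > 0, totals, 1.0)
    if np.allclose(x.std(axis=0), 0.0):
        raise ValueError("airway-bin expression is constant")
    if method == "pca":
        from sklearn.decomposition import PCA
        emb = PCA(n_components=1, random_state=seed).fit_transform(x)[:, 0]
    elif method == "umap":
        import umap
        emb = umap.UMAP(n_components=1, random_state=seed).fit_transform(x)[:, 0]
    else:
        raise ValueError("method must be 'pca' or 'umap'")
    prox = [g for g in proximal_genes if g in grid.gene_ids]
    if prox:
        agg = np.sum([grid.gene_counts(g)[mask] for g in prox], axis=0)
        if np.std(agg) > 0 and np.corrcoef(agg, emb)[0, 1] > 0:
            emb = -emb
    score = 2.0 * _minmax(emb) - 1.0
    out = np.full(grid.n_bins, np.nan)
    out[mask] = score
    return out


def propagate_pd(pd_scores: np.ndarray, airway_mask: np.ndarray,
                 centers: np.ndarray) -> np.ndarray:
    """Give every entity the PD score of its nearest airway bin (Euclidean;
    ties resolved to the lowest airway-bin index). Airway bins keep their
    own score."""
    mask = np.asarray(airway_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty airway mask")
    pd_scores = np.asarray(pd_scores, dtype=float)
    airway_idx = np.flatnonzero(mask)
    d = cdist(centers, centers[mask])
    nearest = d.argmin(axis=1)  # argmin returns the first (lowest-index) tie
    out = pd_scores[airway_idx[nearest]]
    out[mask] = pd_scores[mask]
    return out


def density_map(pd_scores: np.ndarray, radial: np.ndarray,
                clusters: Sequence | None = None,
                fractions: pd.DataFrame | None = None,
                pd_bin: float = 0.1, radial_bin: float = 20.0,
                smooth_sigma: float | None = None) -> dict[str, pd.DataFrame]:
    """Per-cluster occupancy grids over (PD, radial) coordinates.

    ISS mode (``clusters`` given): 2D histogram of entity counts per cluster,
    optionally Gaussian-smoothed (``smooth_sigma`` in grid cells). ST mode
    (``fractions`` given): PD rounded to the ``pd_bin`` grid and radial to the
    ``radial_bin`` grid, then the mean cluster fraction over entities sharing
    the same (PD, radial) cell. Each cluster's grid is normalized to max 1.
    Rows are PD grid values, columns radial grid values.
    """
    if (clusters is None) == (fractions is None):
        raise ValueError("provide exactly one of clusters or fractions")
    pd_scores = np.asarray(pd_scores, dtype=float)
    radial = np.asarray(radial, dtype=float)
    ok = np.isfinite(pd_scores) & np.isfinite(radial)
    if not ok.any():
        raise ValueError("no entities with defined coordinates")
    pd_r = np.round(np.round(pd_scores[ok] / pd_bin) * pd_bin, 9)
    ra_r = np.round(np.round(radial[ok] / radial_bin) * radial_bin, 9)
    pd_axis = np.round(np.arange(-1.0, 1.0 + pd_bin / 2, pd_bin), 9)
    ra_axis = np.unique(ra_r)

    out: dict[str, pd.DataFrame] = {}
    if clusters is not None:
        clusters = np.asarray(clusters)[ok]
        for c in pd.unique(clusters):
            sel = clusters == c
            grid = pd.DataFrame(0.0, index=pd_axis, columns=ra_axis)
            cell = pd.crosstab(pd_r[sel], ra_r[sel])
            grid.loc[cell.index, cell.columns] = cell.astype(float)
            vals = grid.to_numpy()
            if smooth_sigma:
                vals = gaussian_filter(vals, smooth_sigma)
            m = vals.max()
            out[str(c)] = pd.DataFrame(vals / m if m > 0 else vals,
                                       index=pd_axis, columns=ra_axis)
    else:
        frac = fractions.loc[ok] if len(fractions) == len(ok) else fractions
        frac = frac.reset_index(drop=True)
        key = pd.DataFrame({"pd": pd_r, "radial": ra_r})
        for c in frac.columns:
            mean = (
                pd.concat([key, frac[c].rename("v")], axis=1)
                .groupby(["pd", "radial"])["v"].mean().unstack(fill_value=0.0)
            )
            grid = pd.DataFrame(0.0, index=pd_axis, columns=ra_axis)
            grid.loc[mean.index, mean.columns] = mean
            m = grid.to_numpy().max()
            out[str(c)] = grid / m if m > 0 else grid
    return out


def zonation_iss(reads: pd.DataFrame, bin_radius: float = 20.0,
                 geometry: str = "square", airway_gene: str = "EPCAM",
                 airway_min: int = 3, max_radial: float = 140.0,
                 proximal_genes: Sequence[str] = PROXIMAL_GENES,
                 method: str = "pca", seed: int = 0
                 ) -> tuple[BinGrid, pd.DataFrame]:
    """Full ISS zonation pipeline: bin, find airway bins, compute radial and
    PD axes and propagate PD tissue-wide. Returns the grid and a per-bin frame
    (x, y, airway, radial, excluded, pd)."""
    grid = bin_reads(reads, geometry=geometry, radius=bin_radius)
    mask = airway_bins(grid, gene=airway_gene, min_count=airway_min)
    radial, excluded = radial_axis(grid, mask, max_radial=max_radial)
    pd_air = pd_embedding_iss(grid, mask, method=method,
                              proximal_genes=proximal_genes, seed=seed)
    pd_all = propagate_pd(pd_air, mask, grid.centers)
    coords = pd.DataFrame({
        "x": grid.centers[:, 0], "y": grid.centers[:, 1],
        "airway": mask, "radial": radial, "excluded": excluded, "pd": pd_all,
    })
    return grid, coords
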