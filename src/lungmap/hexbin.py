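"""Hexagonal binning and neuroendocrine-bin analysis of SCRINSHOT-like reads.

Sections are tiled with pointy-top hexagons of 7 um circumradius by default
(approximating epithelial cell size); reads are assigned by exact axial
(cube) rounding, so every read lands in the hexagon that contains it and
counts are conserved. Retained bins must show a clear proximal epithelial
component (SOX2 > 3 and EPCAM > 3 molecules) and either at least 12 summed
molecules of the neuroendocrine gene set or more than 10 ASCL1 molecules.
Retained bins are Leiden-clustered (resolution 0.1) on a kNN graph of
normalized count vectors, and gene-gene Pearson correlations across retained
bins summarize marker co-expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NE_GENES = ("ARX", "NKX2-2", "GHRL", "ACSL1", "CALCA", "GRP", "RFX6",
            "CFC1", "PCSK1", "ASCL1")

_SQRT3 = np.sqrt(3.0)


def hex_assign(x: np.ndarray, y: np.ndarray, radius: float,
               orientation: str = "pointy") -> np.ndarray:
    """Axial (q, r) hexagon indices containing each point (cube rounding)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if orientation == "pointy":
        qf = (_SQRT3 / 3.0 * x - y / 3.0) / radius
        rf = (2.0 / 3.0 * y) / radius
    elif orientation == "flat":
        qf = (2.0 / 3.0 * x) / radius
        rf = (-x / 3.0 + _SQRT3 / 3.0 * y) / radius
    else:
        raise ValueError("orientation must be 'pointy' or 'flat'")
    sf = -qf - rf
    q, r, s = np.round(qf), np.round(rf), np.round(sf)
    dq, dr, ds = np.abs(q - qf), np.abs(r - rf), np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q[fix_q] = -r[fix_q] - s[fix_q]
    r[fix_r] = -q[fix_r] - s[fix_r]
    return np.stack([q, r], axis=1).astype(np.int64)


def hex_center(axial: np.ndarray, radius: float,
               orientation: str = "pointy") -> np.ndarray:
    """Cartesian centers of axial hexagon indices."""
    q = axial[:, 0].astype(float)
    r = axial[:, 1].astype(float)
    if orientation == "pointy":
        return np.stack([radius * (_SQRT3 * q + _SQRT3 / 2.0 * r),
                         radius * 1.5 * r], axis=1)
    return np.stack([radius * 1.5 * q,
                     radius * (_SQRT3 / 2.0 * q + _SQRT3 * r)], axis=1)


@dataclass
class HexGrid:
    """Per-hexagon gene counts on a pointy- or flat-top lattice."""

    axial: np.ndarray  # (n_bins, 2) int axial coordinates
    centers: np.ndarray  # (n_bins, 2) um
    counts: np.ndarray  # (n_bins, n_genes)
    gene_ids: np.ndarray
    radius: float
    orientation: str = "pointy"

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def gene_counts(self, gene: str) -> np.ndarray:
        idx = np.flatnonzero(self.gene_ids == gene)
        if len(idx) == 0:
            raise KeyError(f"gene {gene!r} not in grid")
        return self.counts[:, idx[0]]


def hex_bin(reads: pd.DataFrame, circumradius: float = 7.0,
            orientation: str = "pointy",
            size_is: str = "circumradius") -> HexGrid:
    """Bin a read table (columns x, y, gene) into hexagons.

    ``size_is="width"`` interprets ``circumradius`` as the hexagon's
    flat-to-flat width instead (circumradius = width / sqrt(3)).
    """
    if circumradius <= 0:
        raise ValueError("circumradius must be positive")
    if len(reads) == 0:
        raise ValueError("empty read table")
    radius = circumradius / _SQRT3 if size_is == "width" else circumradius
    axial = hex_assign(reads["x"].to_numpy(), reads["y"].to_numpy(),
                       radius, orientation)
    genes = np.array(sorted(reads["gene"].unique()), dtype=object)
    g_idx = {g: j for j, g in enumerate(genes)}
    keys, inverse = np.unique(axial, axis=0, return_inverse=True)
    counts = np.zeros((len(keys), len(genes)), dtype=np.int64)
    cols = reads["gene"].map(g_idx).to_numpy()
    np.add.at(counts, (inverse, cols), 1)
    return HexGrid(axial=keys, centers=hex_center(keys, radius, orientation),
                   counts=counts, gene_ids=genes, radius=radius,
                   orientation=orientation)


def epithelial_filter(grid: HexGrid, sox2_min: int = 3,
                      epcam_min: int = 3) -> np.ndarray:
    """Bins with a clear proximal epithelial component:
    SOX2 > ``sox2_min`` AND EPCAM > ``epcam_min`` (both strict)."""
    return ((grid.gene_counts("SOX2") > sox2_min)
            & (grid.gene_counts("EPCAM") > epcam_min))


def ne_filter(grid: HexGrid, ne_genes: Sequence[str] = NE_GENES,
              sum_min: int = 12, ascl1_min: int = 10,
              return_provenance: bool = False):
    """Neuroendocrine-content filter.

    A bin is kept iff the summed counts of the NE gene set reach ``sum_min``
    (inclusive) OR its ASCL1 count exceeds ``ascl1_min`` (strict). With
    ``return_provenance`` also returns which rule retained each bin.
    """
    present = [g for g in ne_genes if g in grid.gene_ids]
    missing = set(ne_genes) - set(present)
    if missing:
        logger.info("NE genes absent from panel ignored: %s", sorted(missing))
    if not present:
        raise KeyError("none of the NE genes are in the grid panel")
    ne_sum = sum(grid.gene_counts(g) for g in present)
    by_sum = ne_sum >= sum_min
    if "ASCL1" in grid.gene_ids:
        by_ascl1 = grid.gene_counts("ASCL1") > ascl1_min
    else:
        by_ascl1 = np.zeros(grid.n_bins, dtype=bool)
    mask = by_sum | by_ascl1
    if return_provenance:
        rule = np.where(by_sum & by_ascl1, "ne_sum+ascl1",
                        np.where(by_sum, "ne_sum",
                                 np.where(by_ascl1, "ascl1", "")))
        return mask, rule
    return mask


def cluster_bins(grid: HexGrid, mask: np.ndarray, resolution: float = 0.1,
                 n_neighbors: int = 15, seed: int = 0) -> pd.DataFrame:
    """Leiden-cluster retained bins on a kNN graph of their count vectors.

    Counts are library-size normalized to the median retained-bin total and
    log1p-transformed before building the graph. Returns a frame with axial
    and Cartesian bin coordinates plus the Leiden cluster label.
    """
    import anndata as ad
    import scanpy as sc

    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 retained bins to cluster")
    adata = ad.AnnData(
        X=grid.counts[mask].astype(np.float32),
        obs=pd.DataFrame(index=[f"bin{i}" for i in np.flatnonzero(mask)]),
        var=pd.DataFrame(index=grid.gene_ids.astype(str)),
    )
    sc.pp.normalize_total(adata)  # to the median bin total
    sc.pp.log1p(adata)
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, n - 1), use_rep="X",
                    random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                 flavor="leidenalg")
    out = pd.DataFrame({
        "q": grid.axial[mask, 0], "r": grid.axial[mask, 1],
        "x": grid.centers[mask, 0], "y": grid.centers[mask, 1],
        "leiden": adata.obs["leiden"].to_numpy(),
    }, index=adata.obs_names)
    return out


def gene_correlation(grid: HexGrid, mask: np.ndarray | None = None,
                     genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Gene-gene Pearson correlation across retained bins (NaN for constant
    genes)."""
    mask = np.ones(grid.n_bins, dtype=bool) if mask is None else np.asarray(mask)
    genes = list(grid.gene_ids) if genes is None else list(genes)
    mat = np.stack([grid.gene_counts(g)[mask] for g in genes], axis=1)
    df = pd.DataFrame(mat, columns=genes)
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
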