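"""Readers, writers and spot-level quality control for spatial count data.

Containers
----------
``SpotMatrix``
    A Visium-like spots x genes integer count matrix with per-spot (x, y)
    positions in micrometres (image convention: origin top-left, y increasing
    downward).
``SpatialReadTable``
    Decoded molecule tables (HybISS / SCRINSHOT output) are plain pandas
    DataFrames with columns ``x``, ``y`` (um) and ``gene``; :func:`read_read_table`
    validates and returns one.

Formats are deliberately boring: Matrix Market triples (matrix.mtx +
barcodes.tsv + features.tsv) or dense CSV for count matrices, CSV for
coordinates and read tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

READ_TABLE_COLUMNS = ("x", "y", "gene")


@dataclass
class SpotMatrix:
    """Spots x genes count matrix with spot coordinates in micrometres."""

    counts: np.ndarray  # (n_spots, n_genes), non-negative integers
    spot_ids: np.ndarray  # (n_spots,) unique strings
    gene_ids: np.ndarray  # (n_genes,) unique strings
    coords: np.ndarray  # (n_spots, 2) finite floats, um

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if sparse.issparse(self.counts):  # pragma: no cover - defensive
            self.counts = self.counts.toarray()
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.counts.shape
        if self.spot_ids.shape != (n,):
            raise ValueError(f"{len(self.spot_ids)} spot ids for {n} matrix rows")
        if self.gene_ids.shape != (g,):
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} matrix columns")
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords shape {self.coords.shape}, expected {(n, 2)}")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite spot coordinates")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, spot_mask: np.ndarray, gene_mask: np.ndarray) -> "SpotMatrix":
        return SpotMatrix(
            counts=self.counts[np.ix_(spot_mask, gene_mask)],
            spot_ids=self.spot_ids[spot_mask],
            gene_ids=self.gene_ids[gene_mask],
            coords=self.coords[spot_mask],
        )


def _read_coords(coords_path: str | Path, spot_ids: Sequence[str]) -> np.ndarray:
    coords = pd.read_csv(coords_path)
    required = {"spot_id", "x", "y"}
    if not required.issubset(coords.columns):
        raise ValueError(f"coords file must have columns {sorted(required)}")
    coords = coords.set_index("spot_id")
    missing = [s for s in spot_ids if s not in coords.index]
    if missing:
        raise ValueError(f"missing coordinates for spots: {missing[:5]}")
    unknown = set(coords.index) - set(spot_ids)
    if unknown:
        raise ValueError(f"coords contain unknown spot ids: {sorted(unknown)[:5]}")
    return coords.loc[list(spot_ids), ["x", "y"]].to_numpy(dtype=float)


def read_spot_matrix(path: str | Path, coords_path: str | Path) -> SpotMatrix:
    """Read a spots x genes count matrix plus coordinates.

    ``path`` is either a dense CSV (index = spot ids, columns = gene ids) or a
    Matrix Market file whose directory also holds ``barcodes.tsv`` (spot ids)
    and ``features.tsv`` (gene ids); MTX matrices are stored genes x spots, the
    CellRanger convention, and transposed on read. ``coords_path`` is a CSV with
    columns ``spot_id``, ``x``, ``y`` mapping every spot to its position in um.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path)  # genes x spots
        barcodes = path.parent / "barcodes.tsv"
        features = path.parent / "features.tsv"
        if not barcodes.exists() or not features.exists():
            raise FileNotFoundError(
                f"expected barcodes.tsv and features.tsv next to {path}"
            )
        spot_ids = pd.read_csv(barcodes, header=None, sep="\t")[0].astype(str).tolist()
        gene_ids = pd.read_csv(features, header=None, sep="\t")[0].astype(str).tolist()
        counts = np.asarray(sparse.csr_matrix(mat).T.todense())
    else:
        df = pd.read_csv(path, index_col=0)
        spot_ids = df.index.astype(str).tolist()
        gene_ids = df.columns.astype(str).tolist()
        counts = df.to_numpy()
    coords = _read_coords(coords_path, spot_ids)
    return SpotMatrix(counts=counts, spot_ids=np.array(spot_ids, dtype=object),
                      gene_ids=np.array(gene_ids, dtype=object), coords=coords)


def write_spot_matrix(m: SpotMatrix, path: str | Path, coords_path: str | Path) -> None:
    """Write a :class:`SpotMatrix` as dense CSV or MTX triple (by extension)."""
    path = Path(path)
    if path.suffix == ".mtx":
        spio.mmwrite(path, sparse.csr_matrix(m.counts.T))
        pd.Series(m.spot_ids).to_csv(path.parent / "barcodes.tsv", sep="\t",
                                     index=False, header=False)
        pd.Series(m.gene_ids).to_csv(path.parent / "features.tsv", sep="\t",
                                     index=False, header=False)
    else:
        pd.DataFrame(m.counts, index=m.spot_ids, columns=m.gene_ids).to_csv(path)
    pd.DataFrame({"spot_id": m.spot_ids, "x": m.coords[:, 0],
                  "y": m.coords[:, 1]}).to_csv(coords_path, index=False)


def qc_filter_spots(
    m: SpotMatrix,
    min_umi: int = 300,
    min_genes: int = 100,
    min_spots_per_gene: int = 5,
    exclude_genes: Iterable[str] | None = None,
) -> SpotMatrix:
    """Apply the standard Visium spot/gene quality filter.

    Spots with fewer than ``min_umi`` total counts or fewer than ``min_genes``
    detected genes are removed ("fewer than" is strict, so boundary values are
    kept); genes detected in fewer than ``min_spots_per_gene`` of the surviving
    spots are then removed. ``exclude_genes`` optionally drops an annotation
    list (mitochondrial / ribosomal / non-coding) before any counting.
    """
    if exclude_genes is not None:
        drop = set(exclude_genes)
        gene_keep = np.array([g not in drop for g in m.gene_ids], dtype=bool)
        m = m.subset(np.ones(m.n_spots, dtype=bool), gene_keep)

    umi = m.counts.sum(axis=1)
    n_detected = (m.counts > 0).sum(axis=1)
    spot_keep = (umi >= min_umi) & (n_detected >= min_genes)

    reduced = m.counts[spot_keep]
    gene_keep = (reduced > 0).sum(axis=0) >= min_spots_per_gene

    out = m.subset(spot_keep, gene_keep)
    if out.n_spots == 0 or out.n_genes == 0:
        logger.warning("QC filter removed everything (%d spots, %d genes kept)",
                       out.n_spots, out.n_genes)
    return out


def read_read_table(
    path: str | Path,
    panel: Iterable[str] | None = None,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Read a decoded-molecule table (columns ``x``, ``y``, ``gene``).

    ``scale`` converts pixel coordinates to micrometres (um per pixel).
    Records whose gene is not in ``panel`` are dropped with a logged count.
    """
    df = pd.read_csv(path)
    missing = set(READ_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    df = df.copy()
    df["x"] = df["x"].astype(float) * scale
    df["y"] = df["y"].astype(float) * scale
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError("non-finite read coordinates")
    if panel is not None:
        panel = set(panel)
        in_panel = df["gene"].isin(panel)
        n_dropped = int((~in_panel).sum())
        if n_dropped:
            logger.info("dropped %d reads with genes outside the declared panel",
                        n_dropped)
        df = df[in_panel].reset_index(drop=True)
    return df
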