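"""Marker statistics: delta-pct, the marker-acceptance filter, and the
expression filters feeding co-localization and panel design.

"Positive" always means raw count > 0, so delta-pct depends only on the zero
pattern of the matrix. Fold changes are computed on counts library-size
normalized to 10,000 per cell and log2(x + 1) transformed; the fold-change
threshold itself is applied on a natural-log ratio of cluster means by
default (the Seurat-era convention), switchable to log2.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPS = 1e-9


def log_normalize(counts: np.ndarray, target: float = 1e4) -> np.ndarray:
    """Library-size normalize each cell to ``target`` counts, then log2(x+1)."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    scaled = counts / np.where(totals > 0, totals, 1.0) * target
    return np.log2(scaled + 1.0)


def delta_pct(
    counts: np.ndarray,
    labels: Sequence,
    gene_ids: Sequence[str] | None = None,
    log_base: str = "natural",
) -> pd.DataFrame:
    """Per (gene, cluster) marker table.

    Columns: ``pct_in`` (fraction of cluster cells with count > 0),
    ``pct_out`` (same for all other cells), ``delta_pct`` (their difference)
    and ``log_fc`` (log fold change of cluster mean vs rest on log-normalized
    values; natural log by default, ``log_base="log2"`` for base 2).
    """
    counts = np.asarray(counts)
    labels = np.asarray(labels)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters (pct_out undefined otherwise)")
    n_cells, n_genes = counts.shape
    if gene_ids is None:
        gene_ids = np.array([f"g{j}" for j in range(n_genes)], dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)

    positive = counts > 0
    lognorm = log_normalize(counts)
    log = np.log if log_base == "natural" else np.log2
    rows = []
    for c in clusters:
        in_c = labels == c
        pct_in = positive[in_c].mean(axis=0)
        pct_out = positive[~in_c].mean(axis=0)
        mean_in = lognorm[in_c].mean(axis=0)
        mean_out = lognorm[~in_c].mean(axis=0)
        log_fc = log(mean_in + _EPS) - log(mean_out + _EPS)
        rows.append(pd.DataFrame({
            "gene": gene_ids, "cluster": c, "pct_in": pct_in,
            "pct_out": pct_out, "delta_pct": pct_in - pct_out,
            "log_fc": log_fc,
        }))
    return pd.concat(rows, ignore_index=True)


def marker_filter(
    table: pd.DataFrame,
    min_pct_in: float = 0.25,
    min_logfc: float = 0.1,
    min_delta_pct: float = 0.10,
    alpha: float = 0.001,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Marker-acceptance filter: a (gene, cluster) row survives iff the gene
    is expressed in at least ``min_pct_in`` of the cluster's cells, shows at
    least ``min_logfc`` log fold increase and is positive in at least
    ``min_delta_pct`` more cells inside the cluster than outside (all
    inclusive). If the table carries a ``p_value`` column, Bonferroni-adjusted
    values (times ``n_tests``, default the number of rows) must additionally
    be < ``alpha``; a pre-adjusted ``p_adj`` column is used as-is.
    """
    keep = (
        (table["pct_in"] >= min_pct_in)
        & (table["log_fc"] >= min_logfc)
        & (table["delta_pct"] >= min_delta_pct)
    )
    if "p_adj" in table.columns:
        keep &= table["p_adj"] < alpha
    elif "p_value" in table.columns:
        m = n_tests if n_tests is not None else len(table)
        keep &= np.minimum(table["p_value"] * m, 1.0) < alpha
    return table[keep].reset_index(drop=True)


def expression_filter(
    counts: np.ndarray,
    labels: Sequence,
    gene_ids: Sequence[str] | None = None,
    min_mean: float = 0.3,
    min_pct: float | None = 0.25,
    min_delta_pct: float | None = 0.10,
    min_logfc: float | None = 0.10,
) -> list[str]:
    """Genes kept for interactome-style analyses.

    A gene passes iff some cluster has mean log2(normalized + 1) expression
    strictly above ``min_mean`` and, when the optional thresholds are not
    ``None``, that same cluster also meets the positivity (``min_pct``),
    delta-pct and log-fold-change criteria (inclusive). Pass ``min_pct=None``
    (etc.) for the mean-only filter.
    """
    counts = np.asarray(counts)
    table = delta_pct(counts, labels, gene_ids=gene_ids)
    lognorm = log_normalize(counts)
    labels = np.asarray(labels)
    means = {
        c: lognorm[labels == c].mean(axis=0) for c in np.unique(labels)
    }
    gid = table["gene"].to_numpy()
    gene_index = {g: j for j, g in enumerate(pd.unique(gid))}
    mean_col = np.array([means[c][gene_index[g]]
                         for g, c in zip(gid, table["cluster"])])
    ok = mean_col > min_mean
    if min_pct is not None:
        ok &= table["pct_in"].to_numpy() >= min_pct
    if min_delta_pct is not None:
        ok &= table["delta_pct"].to_numpy() >= min_delta_pct
    if min_logfc is not None:
        ok &= table["log_fc"].to_numpy() >= min_logfc
    passed = sorted(set(gid[ok]))
    return passed


def candidate_panel(
    counts: np.ndarray,
    labels: Sequence,
    gene_ids: Sequence[str] | None = None,
    top_n: int = 4,
    min_pct_in: float = 0.25,
    min_logfc: float = 0.1,
    min_delta_pct: float = 0.10,
) -> list[str]:
    """Initial candidate gene panel: the union over clusters of each cluster's
    ``top_n`` accepted markers ranked by delta-pct (ties broken by higher
    log fold change, then lexicographic gene id)."""
    table = delta_pct(counts, labels, gene_ids=gene_ids)
    accepted = marker_filter(table, min_pct_in=min_pct_in, min_logfc=min_logfc,
                             min_delta_pct=min_delta_pct)
    chosen: set[str] = set()
    for c, grp in accepted.groupby("cluster"):
        ranked = grp.sort_values(
            ["delta_pct", "log_fc", "gene"], ascending=[False, False, True]
        )
        if len(ranked) < top_n:
            logger.info("cluster %r has only %d accepted markers (< %d)",
                        c, len(ranked), top_n)
        chosen.update(ranked["gene"].head(top_n))
    return sorted(chosen)
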