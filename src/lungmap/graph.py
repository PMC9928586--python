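"""Cluster-transition graph abstraction for lineage-path inference.

Given a binary shared-nearest-neighbour cell graph G (N x N, symmetric, zero
diagonal) and one-hot cluster assignments O (N x k), the cluster-level
shared-edge matrix is

    E = (G O)^T O,

i.e. E[a, b] counts adjacency entries between cells of cluster b and cells of
cluster a (each undirected edge contributes to both ordered directions;
within-cluster edges count twice on the diagonal). Row-normalizing E
(Hadamard division by E . J, J the all-ones matrix) yields transition
probabilities P; entries below a pruning threshold (default 1e-4) are zeroed
without renormalization; surviving edges get weights w_ij = 1 / p_ij, and
immature-to-mature lineage paths are minimum-weight directed paths found with
Dijkstra's algorithm.
"""

from __future__ import annotations

import heapq
import logging
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def one_hot(labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """One-hot matrix O (N x k) and the sorted cluster id vector."""
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    o = (labels[:, None] == clusters[None, :]).astype(np.int64)
    return o, clusters


def _check_adjacency(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.isin(g, (0, 1)).all():
        raise ValueError("adjacency entries must be 0/1")
    if np.any(np.diag(g) != 0):
        raise ValueError("adjacency must have a zero diagonal (no self-loops)")
    if not np.array_equal(g, g.T):
        raise ValueError("adjacency must be symmetric")
    return g


def shared_edges(g: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Cluster shared-edge count matrix E = (G O)^T O."""
    g = _check_adjacency(g)
    o = np.asarray(o)
    if o.ndim != 2 or o.shape[0] != g.shape[0]:
        raise ValueError("one-hot matrix rows must match adjacency size")
    if not np.isin(o, (0, 1)).all() or not np.all(o.sum(axis=1) == 1):
        raise ValueError("each cell must belong to exactly one cluster")
    return (g @ o).T @ o


def transition_matrix(e: np.ndarray) -> np.ndarray:
    """Row-normalize E into transition probabilities P = E / (E . J).

    Rows with zero edge total (isolated clusters) become zero rows and are
    flagged with a warning.
    """
    e = np.asarray(e, dtype=float)
    if (e < 0).any():
        raise ValueError("E must be non-negative")
    row = e.sum(axis=1, keepdims=True)
    zero = row[:, 0] == 0
    if zero.any():
        logger.warning("clusters with no edges (zero P rows): %s",
                       np.flatnonzero(zero).tolist())
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row > 0, e / np.where(row > 0, row, 1.0), 0.0)
    return p


def prune(p: np.ndarray, p_min: float = 1e-4, renormalize: bool = False) -> np.ndarray:
    """Zero transition probabilities strictly below ``p_min``.

    No renormalization by default, so surviving p values (and hence the
    weights 1/p) are preserved exactly; ``renormalize=True`` rescales the
    remaining entries of each nonzero row to sum to one.
    """
    if p_min < 0:
        raise ValueError("p_min must be >= 0")
    p = np.asarray(p, dtype=float).copy()
    p[p < p_min] = 0.0
    if renormalize:
        row = p.sum(axis=1, keepdims=True)
        p = np.where(row > 0, p / np.where(row > 0, row, 1.0), 0.0)
    return p


def edge_weights(p: np.ndarray) -> np.ndarray:
    """Directed weights w_ij = 1 / p_ij on surviving edges; +inf elsewhere."""
    p = np.asarray(p, dtype=float)
    w = np.full(p.shape, np.inf)
    np.divide(1.0, p, out=w, where=p > 0)
    return w


def optimal_paths(
    w: np.ndarray,
    root: int,
    targets: Sequence[int],
    cluster_ids: Sequence[Hashable] | None = None,
) -> dict:
    """Minimum-total-weight directed path from ``root`` to each target.

    Dijkstra over the k x k weighted cluster graph; ties between equal-weight
    paths are broken by lexicographic order of the cluster index sequence so
    results are deterministic. Unreachable targets are reported as ``None``.
    ``root`` and ``targets`` are indices into ``w`` unless ``cluster_ids`` is
    given, in which case they (and the returned paths) are cluster ids.
    """
    w = np.asarray(w, dtype=float)
    k = w.shape[0]
    if cluster_ids is not None:
        lookup = {c: i for i, c in enumerate(cluster_ids)}
        root_i = lookup[root]
        target_is = [lookup[t] for t in targets]
    else:
        root_i, target_is = root, list(targets)
    if not 0 <= root_i < k:
        raise ValueError(f"root {root!r} not in graph")

    # Dijkstra with (dist, path) keys: the heap order itself realizes the
    # lexicographic tie-break among equal-weight paths. k is small (clusters).
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    heap: list[tuple[float, tuple[int, ...]]] = [(0.0, (root_i,))]
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (dist, path)
        for nbr in range(k):
            if np.isfinite(w[node, nbr]) and nbr not in best:
                heapq.heappush(heap, (dist + w[node, nbr], path + (nbr,)))

    out = {}
    for t_user, t_i in zip(targets, target_is):
        if t_i in best:
            dist, path = best[t_i]
            if cluster_ids is not None:
                path = tuple(cluster_ids[i] for i in path)
            out[t_user] = {"path": list(path), "weight": dist}
        else:
            out[t_user] = None
    return out


def cluster_graph(
    adjacency: np.ndarray,
    labels: Sequence,
    p_min: float = 1e-4,
    renormalize: bool = False,
) -> dict:
    """Full abstraction pipeline: E, P, pruned P and weights, keyed by the
    sorted cluster ids."""
    o, clusters = one_hot(labels)
    e = shared_edges(adjacency, o)
    p = transition_matrix(e)
    p_pruned = prune(p, p_min=p_min, renormalize=renormalize)
    w = edge_weights(p_pruned)
    return {"clusters": clusters, "E": e, "P": p, "P_pruned": p_pruned, "W": w}


def read_edge_list(edges_path, labels_path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (cell_i, cell_j) edge-list CSV plus a (cell, cluster) label CSV
    into an adjacency matrix and aligned label vector."""
    edges = pd.read_csv(edges_path)
    lab = pd.read_csv(labels_path)
    if not {"cell_i", "cell_j"}.issubset(edges.columns):
        raise ValueError("edge list must have columns cell_i, cell_j")
    if not {"cell", "cluster"}.issubset(lab.columns):
        raise ValueError("labels must have columns cell, cluster")
    cells = lab["cell"].tolist()
    index = {c: i for i, c in enumerate(cells)}
    n = len(cells)
    adj = np.zeros((n, n), dtype=np.int8)
    for a, b in edges[["cell_i", "cell_j"]].itertuples(index=False):
        i, j = index[a], index[b]
        if i == j:
            raise ValueError(f"self-loop on cell {a!r}")
        adj[i, j] = adj[j, i] = 1
    return adj, lab["cluster"].to_numpy()
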