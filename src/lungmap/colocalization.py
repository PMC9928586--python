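"""Cell-type co-localization neighbourhoods from spot deconvolution output.

A spot x cell-type fraction matrix (e.g. stereoscope output) is summarized as
a Pearson correlation matrix across spots; thresholding the correlations
(edge iff r strictly above ``r_min``, default 0.04) yields an undirected
graph whose connected components are the spatial "neighbourhoods" of
co-occurring cell types.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


def prepare_fractions(
    fractions: pd.DataFrame,
    exclude: Sequence[str] | None = None,
    merge: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Optionally exclude cell types and merge groups (summing fractions),
    e.g. dropping immune types and pooling neuronal clusters into one."""
    df = fractions.copy()
    if merge:
        for new_name, members in merge.items():
            members = [m for m in members if m in df.columns]
            if members:
                df[new_name] = df[members].sum(axis=1)
                df = df.drop(columns=members)
    if exclude:
        df = df.drop(columns=[c for c in exclude if c in df.columns])
    return df


def fraction_correlations(
    fractions: pd.DataFrame,
    section_ids: Sequence | None = None,
    standardize_per_section: bool = False,
) -> pd.DataFrame:
    """Type x type Pearson correlation of cell-type fractions across spots.

    Spots from all sections are pooled (the published convention);
    ``standardize_per_section=True`` z-scores each type within each section
    first. Constant types yield undefined correlations, reported as NaN.
    """
    if len(fractions) < 3:
        raise ValueError("need at least 3 spots")
    vals = fractions.copy()
    if standardize_per_section:
        if section_ids is None:
            raise ValueError("standardize_per_section requires section_ids")
        sec = np.asarray(section_ids)
        for s in np.unique(sec):
            block = vals.loc[sec == s]
            sd = block.std(ddof=0).replace(0.0, np.nan)
            vals.loc[sec == s] = (block - block.mean()) / sd
    corr = vals.corr(method="pearson")  # pairwise, NaN for constant columns
    np.fill_diagonal(corr.values, 1.0)
    return corr


def neighbourhood_graph(corr: pd.DataFrame, r_min: float = 0.04) -> dict:
    """Threshold the correlation matrix into a co-localization graph.

    Edge (a, b) iff r > ``r_min`` (strict). Returns nodes, edges with their r,
    the connected components (sorted for determinism) and singleton types.
    """
    if not -1.0 <= r_min <= 1.0:
        raise ValueError("r_min must lie in [-1, 1]")
    if not np.allclose(corr.values, corr.values.T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    types = list(corr.columns)
    g = nx.Graph()
    g.add_nodes_from(types)
    for i, a in enumerate(types):
        for b in types[i + 1:]:
            r = corr.at[a, b]
            if np.isfinite(r) and r > r_min:
                g.add_edge(a, b, r=float(r))
    components = sorted(
        (sorted(c) for c in nx.connected_components(g) if len(c) > 1),
        key=lambda c: c[0],
    )
    singletons = sorted(n for n in g.nodes if g.degree[n] == 0)
    return {
        "nodes": types,
        "edges": [(a, b, d["r"]) for a, b, d in g.edges(data=True)],
        "components": components,
        "singletons": singletons,
        "graph": g,
    }
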