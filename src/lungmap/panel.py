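"""Simulation-driven curation of a targeted gene panel.

The loop mirrors how in-situ panels are designed from reference expression
profiles: simulate a spatial field of cells with negative-binomial counts
restricted to the current panel, type every cell with a probabilistic
negative-binomial classifier, score each gene's contribution to typing
accuracy by leave-one-gene-out, and keep the union over cell types of the
top-contributing genes, iterating until every type is predicted at the target
accuracy.

The typer is a per-cell NB maximum-a-posteriori classifier: simulated cells
have known read-to-cell assignment, so segmentation-aware machinery is
unnecessary and the assignment is

    argmax_t  sum_g log NB(count_g | mean_expr[g, t], size) + log prior_t.

Contribution of gene g to type t is the paired accuracy drop
accuracy_t(panel) - accuracy_t(panel \\ {g}) computed on the same simulated
cells, averaged over replicates; a gene with identical means across types
contributes essentially nothing, since its likelihood term is the same for
every type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ExpressionProfiles, simulate_cell_dataset

_MEAN_FLOOR = 1e-6  # avoids -inf log-likelihoods for mean-zero genes


@dataclass
class SimulatedField:
    """Cells scattered uniformly in a rectangle with NB panel counts."""

    positions: np.ndarray  # (n_cells, 2) um
    true_type: np.ndarray
    counts: np.ndarray  # (n_cells, n_panel_genes)
    gene_ids: np.ndarray
    type_ids: np.ndarray

    def restrict(self, genes: Sequence[str]) -> "SimulatedField":
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in genes]
        return SimulatedField(self.positions, self.true_type,
                              self.counts[:, cols],
                              np.asarray(list(genes), dtype=object),
                              self.type_ids)


@dataclass
class PanelResult:
    panel: list[str]
    history: list[dict] = field(default_factory=list)
    contributions: pd.DataFrame | None = None
    converged: bool = False


class NegativeBinomialTyper:
    """Probabilistic NB cell typer with a scikit-learn estimator surface.

    Parameters
    ----------
    dispersion : float
        Shared NB size parameter (variance = mean + mean^2 / dispersion).
    prior : array-like or None
        Class prior over types; uniform when None.
    """

    def __init__(self, dispersion: float = 2.0, prior=None):
        self.dispersion = dispersion
        self.prior = prior

    def get_params(self, deep: bool = True) -> dict:
        return {"dispersion": self.dispersion, "prior": self.prior}

    def set_params(self, **params) -> "NegativeBinomialTyper":
        for k, v in params.items():
            if k not in ("dispersion", "prior"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "NegativeBinomialTyper":
        """Estimate per-type mean expression from labeled counts."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.mean_expr_ = np.stack(
            [X[y == c].mean(axis=0) for c in self.classes_], axis=1
        )
        if not np.any(self.mean_expr_ > 0):
            raise ValueError("all-zero profiles")
        return self

    @classmethod
    def from_profiles(cls, profiles: ExpressionProfiles, prior=None
                      ) -> "NegativeBinomialTyper":
        """Build a fitted typer directly from reference profiles."""
        est = cls(dispersion=profiles.dispersion, prior=prior)
        order = np.argsort(profiles.type_ids.astype(str))
        est.classes_ = profiles.type_ids[order]
        est.mean_expr_ = profiles.mean_expr[:, order]
        if not np.any(est.mean_expr_ > 0):
            raise ValueError("all-zero profiles")
        return est

    def _loglik_per_gene(self, X: np.ndarray) -> np.ndarray:
        """(n_cells, n_genes, n_types) per-gene log-likelihoods."""
        X = np.asarray(X)
        mean = np.maximum(self.mean_expr_, _MEAN_FLOOR)  # (genes, types)
        size = self.dispersion
        p = size / (size + mean)
        return stats.nbinom.logpmf(X[:, :, None], size, p[None, :, :])

    def decision_function(self, X) -> np.ndarray:
        ll = self._loglik_per_gene(X).sum(axis=1)
        k = len(self.classes_)
        prior = np.full(k, 1.0 / k) if self.prior is None else np.asarray(self.prior)
        return ll + np.log(prior)

    def predict_proba(self, X) -> np.ndarray:
        score = self.decision_function(X)
        score -= score.max(axis=1, keepdims=True)
        post = np.exp(score)
        return post / post.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        # argmax returns the first maximum; classes_ is sorted, so ties break
        # lexicographically.
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def simulate_field(
    profiles: ExpressionProfiles,
    panel: Sequence[str],
    n_cells: int,
    field_size: tuple[float, float] = (1000.0, 1000.0),
    type_props: Sequence[float] | None = None,
    seed: int = 0,
) -> SimulatedField:
    """Scatter ``n_cells`` uniformly in a rectangle, assign types (uniform by
    default) and draw NB counts restricted to the panel genes."""
    panel = list(panel)
    if not panel:
        raise ValueError("empty panel")
    sub = profiles.restrict(panel)
    counts, labels = simulate_cell_dataset(n_cells, sub, type_props, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    pos = rng.uniform((0.0, 0.0), field_size, size=(n_cells, 2))
    return SimulatedField(pos, labels, counts, sub.gene_ids, sub.type_ids)


def type_cells(
    field: SimulatedField,
    profiles: ExpressionProfiles,
    panel: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each simulated cell its MAP type. Returns (assigned, posterior)."""
    panel = list(field.gene_ids) if panel is None else list(panel)
    typer = NegativeBinomialTyper.from_profiles(profiles.restrict(panel))
    f = field.restrict(panel)
    return typer.predict(f.counts), typer.predict_proba(f.counts)


def _per_type_accuracy(true: np.ndarray, pred: np.ndarray,
                       type_ids: np.ndarray) -> np.ndarray:
    return np.array([
        (pred[true == t] == t).mean() if np.any(true == t) else np.nan
        for t in type_ids
    ])


def gene_contributions(
    fields: SimulatedField | Sequence[SimulatedField],
    profiles: ExpressionProfiles,
    panel: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Leave-one-gene-out contribution of each panel gene to each type.

    contribution[g, t] = accuracy_t(panel) - accuracy_t(panel without g),
    averaged over the supplied replicate fields (paired on the same cells).
    Also returns the full-panel per-type accuracy averaged over replicates.
    """
    if isinstance(fields, SimulatedField):
        fields = [fields]
    panel = list(fields[0].gene_ids) if panel is None else list(panel)
    if len(panel) < 2:
        raise ValueError("panel must have at least 2 genes")
    typer = NegativeBinomialTyper.from_profiles(profiles.restrict(panel))
    types = typer.classes_
    contrib = np.zeros((len(panel), len(types)))
    acc_full = np.zeros(len(types))
    for fld in fields:
        f = fld.restrict(panel)
        ll_gene = typer._loglik_per_gene(f.counts)  # (cells, genes, types)
        total = ll_gene.sum(axis=1)
        full_pred = types[np.argmax(total, axis=1)]
        a_full = _per_type_accuracy(f.true_type, full_pred, types)
        acc_full += a_full
        for j in range(len(panel)):
            pred_j = types[np.argmax(total - ll_gene[:, j, :], axis=1)]
            contrib[j] += a_full - _per_type_accuracy(f.true_type, pred_j, types)
    contrib /= len(fields)
    acc_full /= len(fields)
    return (pd.DataFrame(contrib, index=panel, columns=types),
            pd.Series(acc_full, index=types))


def curate_panel(
    candidates: Sequence[str],
    profiles: ExpressionProfiles,
    keep_per_type: int = 5,
    accuracy_target: float = 0.95,
    max_iters: int = 10,
    n_cells: int = 3000,
    n_rep: int = 5,
    seed: int = 0,
) -> PanelResult:
    """Iteratively reduce ``candidates`` to a minimal panel typing all cells.

    Each iteration simulates ``n_rep`` replicate fields of ``n_cells`` cells
    on the current panel, computes leave-one-gene-out contributions, keeps the
    union over types of the ``keep_per_type`` top contributors per type (ties
    broken lexicographically) and measures the reduced panel's per-type
    accuracy on the same cells. The loop stops when every type reaches
    ``accuracy_target`` or after ``max_iters``; if the target is never reached
    the best panel seen is returned with ``converged=False``.
    """
    panel = sorted(set(candidates))
    result = PanelResult(panel=panel)
    ss = np.random.SeedSequence(seed)
    best = (-np.inf, panel)
    for it in range(max_iters):
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_rep)]
        fields = [simulate_field(profiles, panel, n_cells, seed=s) for s in seeds]
        contrib, _ = gene_contributions(fields, profiles, panel)
        kept: set[str] = set()
        for t in contrib.columns:
            order = sorted(contrib.index, key=lambda g: (-contrib.at[g, t], g))
            kept.update(order[:keep_per_type])
        new_panel = sorted(kept)
        _, acc_new = gene_contributions(fields, profiles, new_panel)
        result.history.append({
            "iteration": it,
            "panel_size": len(new_panel),
            "accuracy": acc_new.to_dict(),
        })
        if float(acc_new.min()) > best[0]:
            best = (float(acc_new.min()), new_panel)
        result.contributions = contrib
        panel = new_panel
        if bool((acc_new >= accuracy_target).all()):
            result.converged = True
            break
    result.panel = panel if result.converged else best[1]
    return result
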