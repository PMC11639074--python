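"""Multi-view cell-cell-communication (CCC) network construction.

One weighted directed graph over cells per active ligand-receptor pair:
the candidate weight from sender ``i`` to receiver ``j`` is
``E_l[i] * E_r[j] / D[i, j]`` — combined ligand/receptor expression damped
by Euclidean distance — and each sender keeps edges only to its ``k``
nearest spatial neighbours. A pair is *active* when both its ligand and
receptor are detected in more than a fraction ``theta`` of cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .data import LRPair, SpatialExpression

DEFAULT_THETA = 0.15
DEFAULT_K = 5
#: relative clamp for coincident cells: epsilon = this x bounding-box diagonal
EPSILON_DIST_SCALE = 1e-6


class NoActivePairsError(ValueError):
    """No LR pair passed the expression-fraction filter."""


@dataclass
class LRExpressionSummary:
    """Per-cell ligand/receptor levels and expressed-cell fractions.

    ``E_l[i]`` is the geometric mean of the ligand subunit expressions in
    cell ``i`` (a single-subunit ligand is its own expression; any zero
    subunit annihilates the mean — a complex needs all subunits).
    ``xi_l`` is the exact fraction of cells with ``E_l > 0``.
    """

    lr: LRPair
    E_l: np.ndarray
    E_r: np.ndarray
    xi_l: float
    xi_r: float


@dataclass
class CCCView:
    """Weighted directed sender->receiver graph for one LR pair (CSR)."""

    lr: LRPair
    edges: sp.csr_matrix

    @property
    def n_cells(self) -> int:
        return self.edges.shape[0]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(senders, receivers, weights) arrays of the stored edges."""
        coo = sp.coo_matrix(self.edges)
        return coo.row, coo.col, coo.data


@dataclass
class MultiViewCCC:
    """The collection of per-LR views, keyed and ordered by lr id."""

    views: dict[str, CCCView]
    theta: float = DEFAULT_THETA
    k: int = DEFAULT_K

    def __post_init__(self):
        self.views = dict(sorted(self.views.items()))

    @property
    def lr_ids(self) -> list[str]:
        return list(self.views.keys())


def geometric_mean_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise geometric mean of a (n, s) non-negative array; zeros kill it."""
    if X.shape[1] == 1:
        return X[:, 0].copy()
    return np.prod(X, axis=1) ** (1.0 / X.shape[1])


def summarize_lr_expression(
    data: SpatialExpression | None,
    lr: LRPair,
    X: np.ndarray | None = None,
    gene_names: list[str] | None = None,
    expression_eps: float = 0.0,
) -> LRExpressionSummary:
    """Per-cell ligand/receptor summary for one pair.

    Works either from a :class:`SpatialExpression` or from an explicit
    dense matrix (``X`` + ``gene_names``), the latter used when re-deriving
    activity from an imputed matrix. ``expression_eps`` sets the detection
    threshold for counting a cell as expressing (0 for raw counts; small
    positive for continuous imputations).
    """
    if X is None:
        assert data is not None
        X = np.asarray(data.X_obs.todense())
        gene_names = data.gene_names
    idx = {g: j for j, g in enumerate(gene_names)}
    for g in lr.ligand_subunits + lr.receptor_subunits:
        if g not in idx:
            raise KeyError(f"subunit gene {g!r} not in dataset")
    lig = X[:, [idx[g] for g in lr.ligand_subunits]]
    rec = X[:, [idx[g] for g in lr.receptor_subunits]]
    E_l = geometric_mean_rows(np.asarray(lig, dtype=np.float64))
    E_r = geometric_mean_rows(np.asarray(rec, dtype=np.float64))
    n = X.shape[0]
    return LRExpressionSummary(
        lr=lr, E_l=E_l, E_r=E_r,
        xi_l=float(np.count_nonzero(E_l > expression_eps)) / n,
        xi_r=float(np.count_nonzero(E_r > expression_eps)) / n,
    )


def filter_expressed_pairs(
    summaries: list[LRExpressionSummary], theta: float = DEFAULT_THETA
) -> set[str]:
    """Active pairs: both expressed fractions strictly exceed ``theta``."""
    if not 0 < theta < 1:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    return {s.lr.id for s in summaries if s.xi_l > theta and s.xi_r > theta}


def compute_distance_matrix(C: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances, with coincident-cell clamping.

    Off-diagonal distances below ``EPSILON_DIST_SCALE x bounding-box
    diagonal`` are clamped up to that epsilon so the inverse-distance
    weights stay finite; the diagonal stays zero (self-communication is
    excluded downstream).
    """
    C = np.asarray(C, dtype=np.float64)
    if C.shape[0] < 2:
        raise ValueError("need at least 2 cells for a distance matrix")
    D = cdist(C, C)
    span = C.max(axis=0) - C.min(axis=0)
    eps = EPSILON_DIST_SCALE * float(np.hypot(*span))
    if eps == 0.0:
        eps = EPSILON_DIST_SCALE
    off = ~np.eye(len(C), dtype=bool)
    D[off & (D < eps)] = eps
    return D


def _knn_keep_mask(D: np.ndarray, k: int) -> np.ndarray:
    """Boolean (n, n) mask keeping each row's k nearest off-diagonal entries.

    Distance ties are broken toward the smaller cell index.
    """
    n = D.shape[0]
    keep = np.zeros((n, n), dtype=bool)
    col = np.arange(n)
    for i in range(n):
        order = np.lexsort((col, D[i]))
        order = order[order != i]
        keep[i, order[:k]] = True
    return keep


def build_ccc_view(
    summary: LRExpressionSummary, D: np.ndarray, k: int = DEFAULT_K
) -> CCCView:
    """Dense outer-product/distance weights, kNN-sparsified per sender."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(summary.E_l)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.outer(summary.E_l, summary.E_r) / D
    np.fill_diagonal(W, 0.0)
    W[~_knn_keep_mask(D, k)] = 0.0
    return CCCView(lr=summary.lr, edges=sp.csr_matrix(W))


def assemble_multiview(
    data: SpatialExpression,
    lr_table: list[LRPair],
    theta: float = DEFAULT_THETA,
    k: int = DEFAULT_K,
) -> MultiViewCCC:
    """Summaries -> activity filter -> one kNN-sparsified view per pair."""
    summaries = [summarize_lr_expression(data, lr) for lr in lr_table]
    active = filter_expressed_pairs(summaries, theta)
    if not active:
        raise NoActivePairsError(
            f"no active LR pairs at theta={theta}; consider lowering theta")
    D = compute_distance_matrix(data.C)
    views = {
        s.lr.id: build_ccc_view(s, D, k)
        for s in summaries if s.lr.id in active
    }
    return MultiViewCCC(views=views, theta=theta, k=k)


def export_views(multiview: MultiViewCCC, cell_ids: list[str], path) -> None:
    """All views as one long-form edge-list CSV."""
    rows = []
    for lr_id, view in multiview.views.items():
        src, dst, w = view.arrays()
        for s, r, weight in zip(src, dst, w):
            rows.append((cell_ids[s], cell_ids[r], weight, lr_id))
    pd.DataFrame(
        rows, columns=["sender_id", "receiver_id", "weight", "lr_id"]
    ).to_csv(path, index=False)
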