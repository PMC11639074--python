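"""Outer refinement loop: grow the CCC network from the model's own output.

After each training pass the active LR set is re-derived from the imputed
matrix (which is dense, so pairs invisible in the sparse observations can
surface), views present in both generations are blended with coefficient
``alpha`` (old) / ``1 - alpha`` (new), newly activated pairs get fresh
views built from the imputation, and previously active pairs falling below
threshold are retained unchanged. The loop stops when no new view appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ccc import (
    CCCView,
    MultiViewCCC,
    _knn_keep_mask,
    build_ccc_view,
    compute_distance_matrix,
    filter_expressed_pairs,
    summarize_lr_expression,
)
from .data import LRPair, SpatialExpression
from .model import GeneMask, ImputationModel, ImputationResult, ModelConfig, train

DEFAULT_ALPHA = 0.2
DEFAULT_MAX_ITERATIONS = 10
#: imputed value above which a continuous output counts as "expressed"
EXPRESSION_EPS = 1e-6


@dataclass
class IterationState:
    """Carries the evolving graph, model and result across iterations."""

    iteration: int
    multiview: MultiViewCCC
    result: ImputationResult
    model: ImputationModel
    alpha: float = DEFAULT_ALPHA
    converged: bool = False
    history: list[dict] = field(default_factory=list)


def update_lr_set(
    X_hat: np.ndarray,
    lr_table: list[LRPair],
    gene_names: list[str],
    theta: float,
    expression_eps: float = EXPRESSION_EPS,
) -> set[str]:
    """Re-derive the active set from an imputed matrix.

    Expression fractions use a small positive detection threshold since a
    continuous decoder rarely emits exact zeros outside masked columns.
    """
    summaries = [
        summarize_lr_expression(None, lr, X=np.asarray(X_hat),
                                gene_names=gene_names,
                                expression_eps=expression_eps)
        for lr in lr_table
    ]
    return filter_expressed_pairs(summaries, theta)


def blend_view(old_view: CCCView, new_view: CCCView, alpha: float,
               D: np.ndarray | None = None, k: int | None = None) -> CCCView:
    """Edgewise convex combination ``alpha*old + (1-alpha)*new``.

    An edge present on one side only is blended against weight 0. When
    ``D`` and ``k`` are given the blend is re-sparsified to each sender's
    k nearest neighbours (both operands are built on that same support, so
    this keeps density bounded without reordering weights).
    """
    if old_view.lr.id != new_view.lr.id:
        raise ValueError("blending views of different LR pairs")
    # written as old + (1-alpha)(new-old) so identical operands are an
    # exact fixed point in floating point
    W = old_view.edges + (1.0 - alpha) * (new_view.edges - old_view.edges)
    W = np.asarray(W.todense())
    np.fill_diagonal(W, 0.0)
    if D is not None and k is not None:
        W[~_knn_keep_mask(D, k)] = 0.0
    return CCCView(lr=old_view.lr, edges=sp.csr_matrix(W))


def refine(
    state: IterationState,
    data: SpatialExpression,
    lr_table: list[LRPair],
    masks: dict[str, GeneMask] | None,
    config: ModelConfig,
    D: np.ndarray | None = None,
    val_indices=None,
    exclude_indices=None,
) -> IterationState:
    """One outer iteration: re-derive, blend, add, retrain (warm-started)."""
    if D is None:
        D = compute_distance_matrix(data.C)
    theta, k = state.multiview.theta, state.multiview.k
    X_hat = state.result.X_hat
    new_active = update_lr_set(X_hat, lr_table, data.gene_names, theta)
    old_ids = set(state.multiview.views)
    added = sorted(new_active - old_ids)
    by_id = {lr.id: lr for lr in lr_table}

    views: dict[str, CCCView] = {}
    for lr_id, old in state.multiview.views.items():
        if lr_id in new_active:
            summary = summarize_lr_expression(
                None, by_id[lr_id], X=X_hat, gene_names=data.gene_names,
                expression_eps=EXPRESSION_EPS)
            new = build_ccc_view(summary, D, k)
            views[lr_id] = blend_view(old, new, state.alpha, D, k)
        else:
            views[lr_id] = old  # retained unchanged
    for lr_id in added:
        summary = summarize_lr_expression(
            None, by_id[lr_id], X=X_hat, gene_names=data.gene_names,
            expression_eps=EXPRESSION_EPS)
        views[lr_id] = build_ccc_view(summary, D, k)

    multiview = MultiViewCCC(views=views, theta=theta, k=k)
    if not added:
        state.converged = True
        state.history.append({
            "iteration": state.iteration, "n_views": len(views),
            "n_new_views": 0,
            "train_loss": state.result.training_log[-1]["train_loss"]})
        return state

    result, model = train(
        data, multiview, masks, config, model=state.model,
        val_indices=val_indices, exclude_indices=exclude_indices)
    new_state = IterationState(
        iteration=state.iteration + 1, multiview=multiview, result=result,
        model=model, alpha=state.alpha, history=state.history)
    new_state.history.append({
        "iteration": new_state.iteration, "n_views": len(views),
        "n_new_views": len(added),
        "train_loss": result.training_log[-1]["train_loss"]})
    return new_state


def run(
    data: SpatialExpression,
    lr_table: list[LRPair],
    masks: dict[str, GeneMask] | None,
    config: ModelConfig,
    theta: float = 0.15,
    k: int = 5,
    alpha: float = DEFAULT_ALPHA,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    val_indices=None,
    exclude_indices=None,
) -> tuple[ImputationResult, MultiViewCCC, list[dict]]:
    """Full pipeline: initial graph from X_obs, train, refine to convergence.

    The active-pair set only ever grows (dropped pairs are retained), so
    the loop terminates in at most ``max_iterations`` outer rounds; it
    normally stops earlier, when an iteration adds no view.
    """
    from .ccc import assemble_multiview

    multiview = assemble_multiview(data, lr_table, theta=theta, k=k)
    result, model = train(
        data, multiview, masks, config,
        val_indices=val_indices, exclude_indices=exclude_indices)
    state = IterationState(
        iteration=0, multiview=multiview, result=result, model=model,
        alpha=alpha)
    state.history.append({
        "iteration": 0, "n_views": len(multiview.views),
        "n_new_views": len(multiview.views),
        "train_loss": result.training_log[-1]["train_loss"]})
    D = compute_distance_matrix(data.C)
    while state.iteration < max_iterations - 1 and not state.converged:
        prev_n = len(state.multiview.views)
        state = refine(state, data, lr_table, masks, config, D=D,
                       val_indices=val_indices, exclude_indices=exclude_indices)
        assert len(state.multiview.views) >= prev_n, "view set shrank"
    return state.result, state.multiview, state.history


def history_frame(history: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(history,
                        columns=["iteration", "n_views", "n_new_views",
                                 "train_loss"])
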