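"""Cell-specific ligand->gene regulatory scoring and ranking.

The regulatory score of LR pair ``lr`` for gene ``g`` in cell ``c`` is the
entry of that pair's (masked) micro-environment component at ``(c, g)`` —
its literal contribution to the imputed expression. Ranking LR pairs by
this score per (cell, gene) yields a cell-resolved picture of which
signals drive which genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ImputationResult


@dataclass
class RegulatoryRanking:
    """Descending (lr_id, score) list for one (cell, gene) pair."""

    cell: str
    gene: str
    ranked: list[tuple[str, float]]

    @property
    def lr_ids(self) -> list[str]:
        return [lr_id for lr_id, _ in self.ranked]

    def top_k(self, k: int) -> list[str]:
        return self.lr_ids[:k]


def regulatory_score(
    result: ImputationResult,
    lr_id: str,
    cell_index: int,
    gene_index: int,
) -> float:
    """The stored component entry for (lr, cell, gene); no recomputation."""
    if lr_id not in result.components:
        raise KeyError(f"LR pair {lr_id!r} not among trained views")
    comp = result.components[lr_id]
    n, m = comp.shape
    if not (0 <= cell_index < n and 0 <= gene_index < m):
        raise KeyError(
            f"(cell {cell_index}, gene {gene_index}) outside {comp.shape}")
    return float(comp[cell_index, gene_index])


def rank_lr_pairs(
    result: ImputationResult,
    cell_index: int,
    gene_index: int,
    cell_id: str | None = None,
    gene_name: str | None = None,
) -> RegulatoryRanking:
    """All active pairs sorted by score, descending; ties by lr id."""
    scores = [
        (lr_id, regulatory_score(result, lr_id, cell_index, gene_index))
        for lr_id in result.views_used
    ]
    scores.sort(key=lambda item: (-item[1], item[0]))
    return RegulatoryRanking(
        cell=cell_id if cell_id is not None else str(cell_index),
        gene=gene_name if gene_name is not None else str(gene_index),
        ranked=scores,
    )


def aggregate_rankings(
    result: ImputationResult,
    cell_indices: list[int],
    gene_index: int,
) -> list[tuple[str, float]]:
    """Mean score over a cell subset per LR pair, sorted descending."""
    if len(cell_indices) == 0:
        raise ValueError("empty cell subset")
    cells = np.sort(np.asarray(cell_indices))  # order-independent means
    means = [
        (lr_id, float(result.components[lr_id][cells, gene_index].mean()))
        for lr_id in result.views_used
    ]
    means.sort(key=lambda item: (-item[1], item[0]))
    return means


def top_k_jaccard(rankings: list[RegulatoryRanking], K: int = 5) -> np.ndarray:
    """Pairwise Jaccard similarity of the top-K LR sets across rankings."""
    if K < 1:
        raise ValueError("K must be >= 1")
    sets = [set(r.top_k(K)) for r in rankings]
    n = len(sets)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[i] | sets[j]
            sim[i, j] = sim[j, i] = (
                len(sets[i] & sets[j]) / len(union) if union else 1.0)
    return sim


def rankings_frame(rankings: list[RegulatoryRanking]) -> pd.DataFrame:
    """Long-form export: cell_id, gene, rank, lr_id, psi."""
    rows = []
    for r in rankings:
        for rank, (lr_id, psi) in enumerate(r.ranked, start=1):
            rows.append((r.cell, r.gene, rank, lr_id, psi))
    return pd.DataFrame(rows, columns=["cell_id", "gene", "rank", "lr_id", "psi"])
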