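"""Gene ranking from the basis matrix.

Each gene's score is the mass of its row in the fitted basis: genes that
load strongly on any factor rank high.  The robust loss tends to produce
row-sparse bases, which concentrates this score on informative genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["GeneRanking", "score_genes", "select_top", "intersect_selections"]


@dataclass
class GeneRanking:
    """Genes ordered by non-increasing score."""

    gene_ids: list
    scores: np.ndarray
    n_selected: int = 0

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores must have equal length")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be sorted non-increasing")


def score_genes(
    U: np.ndarray, gene_ids: Sequence | None = None, strategy: str = "l1"
) -> GeneRanking:
    """Rank genes by row mass of the non-negative basis ``U``.

    ``strategy='l1'`` scores each row by the sum of absolute loadings
    (the row sum, for non-negative ``U``); ``'l2'`` by the row Euclidean
    norm.  Ties are broken by input gene order (stable sort).
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("U must be 2-D (genes x factors)")
    if np.any(U < 0):
        raise ValueError("U must be non-negative")
    if strategy == "l1":
        scores = np.abs(U).sum(axis=1)
    elif strategy == "l2":
        scores = np.linalg.norm(U, axis=1)
    else:
        raise ValueError("strategy must be 'l1' or 'l2'")
    m = U.shape[0]
    if gene_ids is None:
        gene_ids = list(range(m))
    else:
        gene_ids = list(gene_ids)
        if len(gene_ids) != m:
            raise ValueError("gene_ids length must match rows of U")
    order = np.argsort(-scores, kind="stable")
    return GeneRanking(
        gene_ids=[gene_ids[i] for i in order], scores=scores[order]
    )


def select_top(ranking: GeneRanking, n: int = 100) -> list:
    """First ``n`` gene ids of the ranking."""
    m = len(ranking.gene_ids)
    if n < 1 or n > m:
        raise ValueError(f"n must be in [1, {m}]")
    ranking.n_selected = n
    return ranking.gene_ids[:n]


def intersect_selections(lists: Sequence[Sequence]) -> list:
    """Genes present in every list, ordered as in the first list."""
    if len(lists) < 2:
        raise ValueError("need at least two selections to intersect")
    common = set(lists[0])
    for other in lists[1:]:
        common &= set(other)
    return [g for g in lists[0] if g in common]
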