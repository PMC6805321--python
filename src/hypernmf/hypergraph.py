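"""Hypergraphs over samples and their unnormalized Laplacians.

A hypergraph joins arbitrarily many vertices per hyperedge, so it can
express relations among groups of samples that a pairwise graph cannot.
The construction used here places one hyperedge per sample, containing
that sample (the centroid) and its ``g`` nearest neighbours in Euclidean
distance; the hyperedge weight is a heat-kernel sum with a per-edge
bandwidth equal to the mean squared member distance.

The unnormalized hypergraph Laplacian is

    L = Dv - H W De^{-1} H^T

with ``H`` the binary vertex-by-edge incidence matrix, ``W`` the diagonal
edge-weight matrix, ``Dv`` the vertex-degree diagonal and ``De`` the
edge-degree diagonal.  The second term is exposed separately
(``adjacency_like``) because the coefficient-matrix update of the solver
needs the positive and negative Laplacian parts on opposite sides of a
multiplicative ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

__all__ = [
    "Hypergraph",
    "build_knn_hypergraph",
    "from_edge_list",
    "hypergraph_regularizer",
    "build_simple_graph_laplacian",
]

#: above this vertex count, Laplacian/adjacency are returned sparse
DENSE_LIMIT = 4096


@dataclass
class Hypergraph:
    """A weighted hypergraph with derived degree and Laplacian matrices.

    Attributes
    ----------
    incidence:
        Binary sparse matrix of shape ``(n_vertices, n_hyperedges)``;
        entry ``(v, e)`` is 1 iff vertex ``v`` belongs to hyperedge ``e``.
    edge_weights:
        Non-negative weight ``w(e)`` per hyperedge.
    dense_limit:
        Vertex count up to which ``laplacian`` and ``adjacency_like``
        are materialized as dense arrays.
    """

    incidence: sparse.csr_array
    edge_weights: np.ndarray
    dense_limit: int = DENSE_LIMIT

    vertex_degrees: np.ndarray = field(init=False)
    edge_degrees: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        H = sparse.csr_array(self.incidence)
        data = H.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValueError("incidence entries must be 0 or 1")
        self.incidence = H
        w = np.asarray(self.edge_weights, dtype=float).ravel()
        if w.shape[0] != H.shape[1]:
            raise ValueError("edge_weights length must equal the number of hyperedges")
        if np.any(w < 0):
            raise ValueError("edge weights must be non-negative")
        self.edge_weights = w
        # d(v) = sum_e w(e) H(v, e);  f(e) = sum_v H(v, e)
        self.vertex_degrees = np.asarray(H @ w).ravel()
        self.edge_degrees = np.asarray(H.sum(axis=0)).ravel()
        if np.any(self.edge_degrees < 1):
            raise ValueError("every hyperedge must contain at least one vertex")

    @property
    def n_vertices(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_hyperedges(self) -> int:
        return self.incidence.shape[1]

    def _adjacency_sparse(self) -> sparse.csr_array:
        H = self.incidence
        scale = sparse.dia_array(
            (self.edge_weights / self.edge_degrees, 0),
            shape=(self.n_hyperedges, self.n_hyperedges),
        )
        return sparse.csr_array(H @ scale @ H.T)

    @property
    def adjacency_like(self):
        """H W De^{-1} H^T — the subtracted part of the Laplacian."""
        E = self._adjacency_sparse()
        if self.n_vertices <= self.dense_limit:
            return E.toarray()
        return E

    @property
    def laplacian(self):
        """Unnormalized hypergraph Laplacian Dv - H W De^{-1} H^T."""
        E = self._adjacency_sparse()
        L = sparse.dia_array(
            (self.vertex_degrees, 0), shape=(self.n_vertices, self.n_vertices)
        ) - E
        if self.n_vertices <= self.dense_limit:
            return L.toarray()
        return sparse.csr_array(L)

    def to_edge_tsv(self, membership_path, weight_path) -> None:
        """Write (edge_id, vertex_id) membership and per-edge weight tables."""
        coo = sparse.coo_array(self.incidence)
        order = np.lexsort((coo.row, coo.col))
        with open(membership_path, "w") as fh:
            fh.write("edge_id\tvertex_id\n")
            for r, c in zip(coo.row[order], coo.col[order]):
                fh.write(f"{c}\t{r}\n")
        with open(weight_path, "w") as fh:
            fh.write("edge_id\tweight\n")
            for e, w in enumerate(self.edge_weights):
                fh.write(f"{e}\t{w:.17g}\n")


def from_edge_list(
    edges: Sequence[Sequence[int]],
    weights: np.ndarray | None = None,
    n_vertices: int | None = None,
    dense_limit: int = DENSE_LIMIT,
) -> Hypergraph:
    """Build a :class:`Hypergraph` from explicit vertex-index sets.

    ``weights`` defaults to 1 for every hyperedge.  Vertex count is
    inferred from the largest index unless given.
    """
    if len(edges) == 0:
        raise ValueError("need at least one hyperedge")
    for e in edges:
        if len(e) == 0:
            raise ValueError("hyperedges must be non-empty")
    max_idx = max(max(e) for e in edges)
    n = int(max_idx) + 1 if n_vertices is None else int(n_vertices)
    if n <= max_idx:
        raise ValueError("n_vertices too small for the given edges")
    rows, cols = [], []
    for j, e in enumerate(edges):
        members = sorted(set(int(v) for v in e))
        if any(v < 0 for v in members):
            raise ValueError("vertex indices must be non-negative")
        rows.extend(members)
        cols.extend([j] * len(members))
    H = sparse.csr_array(
        (np.ones(len(rows)), (rows, cols)), shape=(n, len(edges))
    )
    if weights is None:
        weights = np.ones(len(edges))
    return Hypergraph(H, np.asarray(weights, dtype=float), dense_limit=dense_limit)


def build_knn_hypergraph(
    points: np.ndarray, g: int, dense_limit: int = DENSE_LIMIT
) -> Hypergraph:
    """One hyperedge per point: the centroid plus its ``g`` nearest neighbours.

    The weight of hyperedge ``e_i`` is ``sum_{j in e_i} exp(-d_ij^2 / delta_i)``
    where ``delta_i`` is the mean of the member squared distances,
    ``(1/g) * sum_{j in e_i} d_ij^2``.  The centroid's own term contributes
    ``exp(0) = 1``.  When all members coincide with the centroid
    (``delta_i = 0``) the weight is the continuous limit ``g + 1``.

    Ties in neighbour distance are broken by ascending point index.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2:
        raise ValueError("points must be a 2-D array (n_samples, n_features)")
    if np.any(~np.isfinite(P)):
        raise ValueError("points must be finite (no NaN/inf)")
    n = P.shape[0]
    if g < 1:
        raise ValueError("neighbour count g must be >= 1")
    if n < g + 1:
        raise ValueError(f"need at least g+1={g + 1} points, got {n}")

    d2 = cdist(P, P, metric="sqeuclidean")
    edges: list[list[int]] = []
    weights = np.empty(n)
    for i in range(n):
        order = np.argsort(d2[i], kind="stable")
        neighbours = [int(j) for j in order if j != i][:g]
        members = [i] + neighbours
        sq = d2[i, members]
        delta = sq.sum() / g
        if delta == 0.0:
            weights[i] = float(g + 1)
        else:
            weights[i] = float(np.exp(-sq / delta).sum())
        edges.append(members)
    return from_edge_list(edges, weights, n_vertices=n, dense_limit=dense_limit)


def hypergraph_regularizer(V: np.ndarray, laplacian) -> float:
    """Smoothness penalty ``Tr(V L V^T)`` of coefficient columns on the graph.

    Equals half the weighted sum over hyperedges of pairwise squared
    differences between member columns, with pair weight ``w(e)/f(e)``.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-D (k, n)")
    n = V.shape[1]
    if laplacian.shape != (n, n):
        raise ValueError(
            f"Laplacian shape {laplacian.shape} does not match n={n} columns of V"
        )
    Y = laplacian @ V.T  # works for dense and sparse
    return float(np.sum(V.T * Y))


def build_simple_graph_laplacian(
    points: np.ndarray, g: int, weighting: str = "binary"
) -> np.ndarray:
    """Mutual-kNN simple-graph Laplacian (pairwise-graph ablation).

    An edge (i, j) exists iff i is among j's ``g`` nearest neighbours and
    vice versa.  ``weighting='binary'`` gives 0/1 edges; ``'heat'`` weights
    each kept edge by ``exp(-d_ij^2 / sigma^2)`` with ``sigma^2`` the mean
    squared distance over kept edges.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2:
        raise ValueError("points must be a 2-D array (n_samples, n_features)")
    if np.any(~np.isfinite(P)):
        raise ValueError("points must be finite (no NaN/inf)")
    n = P.shape[0]
    if g < 1:
        raise ValueError("neighbour count g must be >= 1")
    if n < g + 1:
        raise ValueError(f"need at least g+1={g + 1} points, got {n}")
    if weighting not in ("binary", "heat"):
        raise ValueError("weighting must be 'binary' or 'heat'")

    d2 = cdist(P, P, metric="sqeuclidean")
    knn = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = np.argsort(d2[i], kind="stable")
        neighbours = [int(j) for j in order if j != i][:g]
        knn[i, neighbours] = True
    A = (knn & knn.T).astype(float)
    if weighting == "heat":
        kept = A > 0
        if kept.any():
            sigma2 = d2[kept].mean()
            if sigma2 > 0:
                A[kept] = np.exp(-d2[kept] / sigma2)
    L = np.diag(A.sum(axis=1)) - A
    return (L + L.T) / 2.0
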