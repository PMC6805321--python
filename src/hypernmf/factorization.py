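"""Multiplicative-update non-negative matrix factorization with a robust
per-sample loss and optional manifold regularization.

The full objective minimized over non-negative ``U`` (m x k basis) and
``V`` (k x n coefficients) is

    sum_j || x_j - U v_j ||_2  +  alpha * Tr(V L V^T)

i.e. the sum of per-sample (column) residual norms — the L2,1 norm of the
transposed residual — plus a graph/hypergraph smoothness penalty on the
sample embedding.  Because each sample's error enters unsquared, samples
with huge residuals (outliers) cannot dominate the fit; the solver
re-weights samples each sweep by ``D_jj = 1 / sqrt(||x_j - U v_j||^2 + gamma)``
and solves the weighted least-squares surrogate with multiplicative updates:

    u_ik <- u_ik * (X D V^T)_ik / (U V D V^T)_ik
    v_kj <- v_kj * (U^T X D + alpha V E)_kj / (U^T U V D + alpha V Dv)_kj

where ``L = Dv - E`` splits the Laplacian into its diagonal-degree and
adjacency-like parts.  Degenerate configurations recover the classical
family: squared (Frobenius) loss fixes ``D = I``; ``manifold='none'``
drops the penalty (plain NMF / NMF-L2,1); ``manifold='simple_graph'``
uses a pairwise mutual-kNN Laplacian (GNMF / robust GNMF); and
``manifold='hypergraph'`` with the robust loss is the full method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .hypergraph import build_knn_hypergraph, build_simple_graph_laplacian

__all__ = [
    "FitConfig",
    "FactorizationResult",
    "VARIANTS",
    "variant_config",
    "l21_norm",
    "residual_weights",
    "objective",
    "update_U",
    "update_V",
    "init_factors",
    "fit",
    "ALPHA_GRID",
]

EPS = 1e-12

NORMS = ("l21", "frobenius")
MANIFOLDS = ("none", "simple_graph", "hypergraph")

#: regularization-strength grid used for cross-validated selection
ALPHA_GRID = tuple(10.0 ** r for r in range(-5, 6))

#: named degenerate configurations of the solver
VARIANTS = {
    "nmf": {"norm": "frobenius", "manifold": "none"},
    "nmf-l21": {"norm": "l21", "manifold": "none"},
    "gnmf": {"norm": "frobenius", "manifold": "simple_graph"},
    "hnmf": {"norm": "frobenius", "manifold": "hypergraph"},
    "rgnmf": {"norm": "l21", "manifold": "simple_graph"},
    "rhnmf": {"norm": "l21", "manifold": "hypergraph"},
}


@dataclass(frozen=True)
class FitConfig:
    """Solver configuration.

    ``k`` is the factorization rank, ``alpha`` the manifold penalty weight,
    ``g`` the neighbour count of the kNN (hyper)graph, ``gamma`` the small
    smoothing constant in the residual re-weighting, ``tol`` the relative
    objective-change stopping threshold.
    """

    k: int
    alpha: float = 0.0
    norm: str = "l21"
    manifold: str = "hypergraph"
    g: int = 5
    max_iter: int = 1000
    tol: float = 1e-6
    gamma: float = 1e-8
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("rank k must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.norm not in NORMS:
            raise ValueError(f"norm must be one of {NORMS}")
        if self.manifold not in MANIFOLDS:
            raise ValueError(f"manifold must be one of {MANIFOLDS}")
        if self.g < 1:
            raise ValueError("g must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


def variant_config(name: str, k: int, **overrides) -> FitConfig:
    """Named ablation configuration ('nmf', 'gnmf', 'hnmf', 'rgnmf', ...)."""
    key = name.lower().replace("_", "-")
    if key not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    params = dict(VARIANTS[key])
    params.update(overrides)
    return FitConfig(k=k, **params)


@dataclass
class FactorizationResult:
    """Fitted factors plus diagnostics.

    ``final_residual_weights`` holds the per-sample re-weighting diagonal
    computed from the final factors (all ones under the squared loss);
    small values flag samples the robust loss down-weighted as outliers.
    """

    U: np.ndarray
    V: np.ndarray
    objective_trajectory: np.ndarray
    final_residual_weights: np.ndarray
    iterations_run: int
    converged: bool
    config: FitConfig | None = field(default=None, repr=False)


def l21_norm(M: np.ndarray) -> float:
    """Sum of row-wise Euclidean norms."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("l21_norm expects a 2-D matrix")
    return float(np.linalg.norm(M, axis=1).sum())


def residual_weights(
    X: np.ndarray, U: np.ndarray, V: np.ndarray, gamma: float
) -> np.ndarray:
    """Per-sample weights ``1 / sqrt(||x_j - U v_j||^2 + gamma)``."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    R = X - U @ V
    sq = np.einsum("ij,ij->j", R, R)
    return 1.0 / np.sqrt(sq + gamma)


def objective(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    L=None,
    alpha: float = 0.0,
    norm: str = "l21",
) -> float:
    """Value of the fitting objective.

    With ``norm='l21'`` the data term is the sum of per-sample (column)
    residual norms, ``l21_norm((X - U V).T)``; with ``'frobenius'`` it is
    the squared Frobenius residual.  The penalty ``alpha * Tr(V L V^T)``
    is added when ``L`` is given and ``alpha > 0``.
    """
    if norm not in NORMS:
        raise ValueError(f"norm must be one of {NORMS}")
    X = np.asarray(X, dtype=float)
    if X.shape != (U.shape[0], V.shape[1]) or U.shape[1] != V.shape[0]:
        raise ValueError("X, U, V shapes do not conform")
    R = X - U @ V
    if norm == "l21":
        data_term = l21_norm(R.T)
    else:
        data_term = float(np.sum(R * R))
    if L is not None and alpha > 0:
        Y = L @ V.T
        data_term += alpha * float(np.sum(V.T * Y))
    return data_term


def update_U(
    X: np.ndarray, U: np.ndarray, V: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """One multiplicative basis update with sample weights ``d`` (diag of D)."""
    numer = (X * d) @ V.T
    denom = U @ ((V * d) @ V.T)
    return U * numer / np.maximum(denom, EPS)


def update_V(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    d: np.ndarray,
    laplacian_parts=None,
    alpha: float = 0.0,
) -> np.ndarray:
    """One multiplicative coefficient update.

    ``laplacian_parts`` is ``(E, dv)``: the adjacency-like matrix and the
    vertex-degree vector with ``L = diag(dv) - E``; ``E`` enters the
    numerator and ``dv`` the denominator so both stay non-negative.
    """
    numer = U.T @ (X * d)
    denom = (U.T @ U) @ (V * d)
    if laplacian_parts is not None and alpha > 0:
        E, dv = laplacian_parts
        numer = numer + alpha * (E @ V.T).T  # E symmetric: V E == (E V^T)^T
        denom = denom + alpha * (V * dv)
    return V * numer / np.maximum(denom, EPS)


def init_factors(
    X: np.ndarray, k: int, seed: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform initialization scaled to the data magnitude."""
    m, n = X.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), EPS) / k)
    U = rng.uniform(size=(m, k)) * scale
    V = rng.uniform(size=(k, n)) * scale
    return U, V


def _laplacian_parts(X: np.ndarray, config: FitConfig):
    """(E, dv, L) for the configured manifold, built on sample columns."""
    points = X.T
    if config.manifold == "hypergraph":
        hg = build_knn_hypergraph(points, config.g)
        E = hg.adjacency_like
        if not isinstance(E, np.ndarray):
            E = E.toarray()
        dv = hg.vertex_degrees
    else:  # simple_graph
        L = build_simple_graph_laplacian(points, config.g)
        dv = np.diag(L).copy()
        E = np.diag(dv) - L
        return E, dv, L
    L = np.diag(dv) - E
    return E, dv, L


def fit(X, config: FitConfig) -> FactorizationResult:
    """Alternate residual re-weighting and multiplicative U/V updates.

    Stops when the relative objective change drops below ``config.tol``
    or after ``config.max_iter`` sweeps.  Accepts a plain array or any
    object with a ``.values`` array (genes in rows, samples in columns).
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix (genes x samples)")
    if np.any(~np.isfinite(X)):
        raise ValueError("X contains NaN or infinite entries")
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    m, n = X.shape
    if config.k > min(m, n):
        raise ValueError(f"rank k={config.k} exceeds min(m, n)={min(m, n)}")

    use_manifold = config.manifold != "none" and config.alpha > 0
    if use_manifold:
        E, dv, L = _laplacian_parts(X, config)
        parts = (E, dv)
        alpha = config.alpha
    else:
        parts, L, alpha = None, None, 0.0

    U, V = init_factors(X, config.k, config.seed)
    ones = np.ones(n)
    trajectory = [objective(X, U, V, L, alpha, config.norm)]
    converged = False
    iterations = 0
    for _ in range(config.max_iter):
        if config.norm == "l21":
            d = residual_weights(X, U, V, config.gamma)
        else:
            d = ones
        U = update_U(X, U, V, d)
        V = update_V(X, U, V, d, parts, alpha)
        obj = objective(X, U, V, L, alpha, config.norm)
        iterations += 1
        prev = trajectory[-1]
        trajectory.append(obj)
        if abs(prev - obj) <= config.tol * max(abs(prev), EPS):
            converged = True
            break

    if config.norm == "l21":
        final_d = residual_weights(X, U, V, config.gamma)
    else:
        final_d = ones.copy()
    return FactorizationResult(
        U=U,
        V=V,
        objective_trajectory=np.asarray(trajectory),
        final_residual_weights=final_d,
        iterations_run=iterations,
        converged=converged,
        config=config,
    )
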