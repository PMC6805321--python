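"""Clustering of the sample embedding and partition-agreement scoring.

Samples are clustered by k-means on the columns of the coefficient matrix.
Agreement with ground truth is scored by clustering accuracy (fraction
matched after the optimal one-to-one relabeling, found by the Hungarian
algorithm on the confusion matrix) and by mutual information normalized
by the larger of the two partition entropies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold

from .factorization import ALPHA_GRID, FitConfig, fit

__all__ = [
    "ClusteringEvaluation",
    "RepeatedEvaluation",
    "cluster_coefficients",
    "best_mapping",
    "accuracy",
    "nmi",
    "evaluate_clustering",
    "select_alpha",
    "repeated_evaluation",
]


def cluster_coefficients(
    V: np.ndarray, n_clusters: int, seed: int | None = 0, n_init: int = 10
) -> np.ndarray:
    """K-means labels (1-based) for the columns of ``V``."""
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    if n_clusters < 1 or n_clusters > n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    return km.fit_predict(V.T) + 1


def _contingency(pred, true) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if pred.size == 0:
        raise ValueError("label vectors must be non-empty")
    p_vals, p_idx = np.unique(pred, return_inverse=True)
    t_vals, t_idx = np.unique(true, return_inverse=True)
    C = np.zeros((p_vals.size, t_vals.size), dtype=int)
    np.add.at(C, (p_idx, t_idx), 1)
    return C, p_vals, t_vals


def best_mapping(pred_labels, true_labels) -> dict:
    """Injective predicted-to-true label map maximizing the match count.

    Found by maximum-weight assignment on the confusion matrix.  When the
    two partitions use different numbers of labels, only ``min`` of them
    are mapped; unmapped predicted labels are absent from the dict.
    """
    C, p_vals, t_vals = _contingency(pred_labels, true_labels)
    rows, cols = linear_sum_assignment(C, maximize=True)
    return {p_vals[r]: t_vals[c] for r, c in zip(rows, cols)}


def accuracy(pred_labels, true_labels) -> float:
    """Fraction of samples matched under the optimal label mapping."""
    C, _, _ = _contingency(pred_labels, true_labels)
    rows, cols = linear_sum_assignment(C, maximize=True)
    return float(C[rows, cols].sum()) / C.sum()


def nmi(pred_labels, true_labels) -> float:
    """Mutual information over the max of the two partition entropies.

    Returns 0 when either partition has a single class (zero entropy).
    """
    C, _, _ = _contingency(pred_labels, true_labels)
    n = C.sum()
    pij = C / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    mi = float(np.sum(pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz])))
    h_pred = float(-np.sum(pi[pi > 0] * np.log(pi[pi > 0])))
    h_true = float(-np.sum(pj[pj > 0] * np.log(pj[pj > 0])))
    h_max = max(h_pred, h_true)
    if h_max == 0.0:
        return 0.0
    return float(min(1.0, max(0.0, mi / h_max)))


@dataclass
class ClusteringEvaluation:
    """Predicted labels scored against ground truth."""

    predicted_labels: np.ndarray
    true_labels: np.ndarray
    mapping: dict
    ac: float
    nmi: float


def evaluate_clustering(pred_labels, true_labels) -> ClusteringEvaluation:
    return ClusteringEvaluation(
        predicted_labels=np.asarray(pred_labels),
        true_labels=np.asarray(true_labels),
        mapping=best_mapping(pred_labels, true_labels),
        ac=accuracy(pred_labels, true_labels),
        nmi=nmi(pred_labels, true_labels),
    )


def select_alpha(
    X,
    labels,
    grid=None,
    n_folds: int = 5,
    config: FitConfig | None = None,
    seed: int | None = 0,
) -> float:
    """Pick the penalty weight by stratified k-fold clustering accuracy.

    For each candidate alpha the model is fitted once on the full matrix;
    accuracy is scored separately on each held-out fold's samples and
    averaged.  Ties go to the smallest alpha.
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    labels = np.asarray(labels)
    n = X.shape[1]
    if labels.shape[0] != n:
        raise ValueError("labels length must match the number of samples")
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, got {n}")
    if grid is None:
        grid = ALPHA_GRID
    grid = sorted(float(a) for a in grid)
    if not grid:
        raise ValueError("alpha grid must be non-empty")
    n_classes = np.unique(labels).size
    if config is None:
        config = FitConfig(k=n_classes, norm="l21", manifold="hypergraph", seed=seed)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(X.T, labels)]

    best_alpha, best_score = None, -np.inf
    for alpha in grid:
        result = fit(X, replace(config, alpha=alpha))
        pred = cluster_coefficients(result.V, n_classes, seed=seed)
        score = float(
            np.mean([accuracy(pred[idx], labels[idx]) for idx in folds])
        )
        if score > best_score:  # ties keep the earlier (smaller) alpha
            best_alpha, best_score = alpha, score
    return best_alpha


@dataclass
class RepeatedEvaluation:
    """Mean and spread of accuracy/NMI over re-seeded runs."""

    ac_values: np.ndarray
    nmi_values: np.ndarray

    @property
    def ac_mean(self) -> float:
        return float(np.mean(self.ac_values))

    @property
    def ac_std(self) -> float:
        return float(np.std(self.ac_values))

    @property
    def nmi_mean(self) -> float:
        return float(np.mean(self.nmi_values))

    @property
    def nmi_std(self) -> float:
        return float(np.std(self.nmi_values))

    def summary(self) -> str:
        """'AC xx.xx ± y.yy % | NMI xx.xx ± y.yy %' table row."""
        return (
            f"AC {100 * self.ac_mean:.2f} ± {100 * self.ac_std:.2f} % | "
            f"NMI {100 * self.nmi_mean:.2f} ± {100 * self.nmi_std:.2f} %"
        )


def repeated_evaluation(
    X, config: FitConfig, true_labels, n_runs: int, base_seed: int = 0
) -> RepeatedEvaluation:
    """Fit + cluster + score ``n_runs`` times with distinct seeds."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    true_labels = np.asarray(true_labels)
    n_classes = np.unique(true_labels).size
    acs, nmis = [], []
    for r in range(n_runs):
        seed = base_seed + r
        result = fit(X, replace(config, seed=seed))
        pred = cluster_coefficients(result.V, n_classes, seed=seed)
        acs.append(accuracy(pred, true_labels))
        nmis.append(nmi(pred, true_labels))
    return RepeatedEvaluation(np.asarray(acs), np.asarray(nmis))
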