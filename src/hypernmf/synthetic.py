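"""Block-structured non-negative test data with ground truth.

Generates an expression-like matrix ``X = U* V* + noise`` where each of
``c`` sample classes activates one factor and a disjoint set of planted
high-loading genes.  A configurable fraction of sample columns is
replaced by large heavy-tailed noise (outliers), which is what the robust
loss is supposed to shrug off.  Multiple datasets sharing the gene axis
can be concatenated column-wise to emulate multi-view matrices where each
view is one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SyntheticDataset", "generate", "multiview_concat"]

#: cap on |Cauchy| draws used for outlier columns
OUTLIER_CAP = 50.0


@dataclass
class SyntheticDataset:
    X: np.ndarray
    true_labels: np.ndarray
    true_U: np.ndarray | None
    true_V: np.ndarray | None
    outlier_mask: np.ndarray
    params: dict


def generate(
    m: int = 300,
    n: int = 150,
    c: int = 3,
    k: int | None = None,
    noise_sd: float = 0.1,
    outlier_fraction: float = 0.0,
    outlier_scale: float = 5.0,
    planted_gene_count: int = 20,
    background: float = 0.05,
    seed: int | None = 0,
) -> SyntheticDataset:
    """Sample a seeded block-structured dataset.

    Labels are balanced to within one sample.  ``true_V`` is a class
    indicator (amplitude jittered in [0.8, 1.2]) over a small uniform
    background; ``true_U`` gives class ``i`` the planted gene rows
    ``[i * planted_gene_count, (i+1) * planted_gene_count)`` with loadings
    in [1, 2] over a background in [0, 0.1].  Gaussian noise is added and
    the matrix clipped at zero; outlier columns are replaced by
    ``outlier_scale`` times capped |Cauchy| draws.
    """
    if m < 1 or n < 1 or c < 1:
        raise ValueError("m, n, c must all be >= 1")
    if not (0.0 <= outlier_fraction < 1.0):
        raise ValueError("outlier_fraction must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if k is None:
        k = c
    if k < c:
        raise ValueError("k must be >= c (one factor per class)")
    if c * planted_gene_count > m:
        raise ValueError("c * planted_gene_count must not exceed m")

    rng = np.random.default_rng(seed)
    labels = np.arange(n) % c

    V = background * rng.uniform(size=(k, n))
    V[labels, np.arange(n)] += rng.uniform(0.8, 1.2, size=n)

    U = rng.uniform(0.0, 0.1, size=(m, k))
    for cls in range(c):
        rows = slice(cls * planted_gene_count, (cls + 1) * planted_gene_count)
        U[rows, cls] = rng.uniform(1.0, 2.0, size=planted_gene_count)

    X = U @ V
    if noise_sd > 0:
        X = np.clip(X + rng.normal(0.0, noise_sd, size=(m, n)), 0.0, None)

    outlier_mask = np.zeros(n, dtype=bool)
    n_out = int(round(outlier_fraction * n))
    if n_out > 0:
        idx = rng.choice(n, size=n_out, replace=False)
        outlier_mask[idx] = True
        draws = np.minimum(np.abs(rng.standard_cauchy(size=(m, n_out))), OUTLIER_CAP)
        X[:, idx] = outlier_scale * draws

    params = dict(
        m=m,
        n=n,
        c=c,
        k=k,
        noise_sd=noise_sd,
        outlier_fraction=outlier_fraction,
        outlier_scale=outlier_scale,
        planted_gene_count=planted_gene_count,
        background=background,
        seed=seed,
    )
    return SyntheticDataset(X, labels, U, V, outlier_mask, params)


def multiview_concat(datasets: Sequence[SyntheticDataset]) -> SyntheticDataset:
    """Column-wise concatenation of views sharing the gene axis.

    Each input dataset becomes one class in the combined labels (view
    index), matching the multi-view convention where every view holds
    samples of a single condition.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    m = datasets[0].X.shape[0]
    for ds in datasets:
        if ds.X.shape[0] != m:
            raise ValueError("all views must share the same gene dimension")
    if len(datasets) == 1:
        return datasets[0]
    X = np.hstack([ds.X for ds in datasets])
    labels = np.concatenate(
        [np.full(ds.X.shape[1], i) for i, ds in enumerate(datasets)]
    )
    outlier_mask = np.concatenate([ds.outlier_mask for ds in datasets])
    params = dict(views=[ds.params for ds in datasets], m=m, n=int(X.shape[1]))
    return SyntheticDataset(X, labels, None, None, outlier_mask, params)
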