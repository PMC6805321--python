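"""Delimited-text readers/writers and the end-to-end pipeline.

The matrix format is genes in rows and samples in columns: first column
gene ids, header row sample ids, tab-separated by default (comma for
``.csv``).  Gzipped files are read transparently.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import cluster_coefficients, evaluate_clustering
from .factorization import FitConfig, fit
from .feature_selection import score_genes, select_top
from .synthetic import generate

__all__ = [
    "ExpressionMatrix",
    "RunManifest",
    "PipelineConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "write_trajectory",
    "run_pipeline",
]


@dataclass
class ExpressionMatrix:
    """Non-negative matrix with gene (row) and sample (column) identifiers."""

    values: np.ndarray
    gene_ids: list
    sample_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length must match the number of rows")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length must match the number of columns")

    @property
    def shape(self):
        return self.values.shape


def _sep_for(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes-by-samples matrix, rejecting NaN and negative cells."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        rows, cols = np.nonzero(np.isnan(values))
        cells = [
            f"(gene={df.index[r]}, sample={df.columns[c]})"
            for r, c in list(zip(rows, cols))[:5]
        ]
        raise ValueError(f"{path}: NaN entries at {', '.join(cells)}")
    if (values < 0).any():
        rows, cols = np.nonzero(values < 0)
        r, c = rows[0], cols[0]
        raise ValueError(
            f"{path}: negative value {values[r, c]} at "
            f"(gene={df.index[r]}, sample={df.columns[c]})"
        )
    return ExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
    )


def write_expression_matrix(path, matrix: ExpressionMatrix) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids
    )
    df.to_csv(path, sep=_sep_for(path))


def write_matrix(path, values, row_ids, col_ids) -> None:
    pd.DataFrame(values, index=row_ids, columns=col_ids).to_csv(
        path, sep=_sep_for(path)
    )


def read_labels(path) -> np.ndarray:
    """One label per line, order matching the sample columns."""
    with open(path) as fh:
        labels = [line.strip() for line in fh if line.strip()]
    if not labels:
        raise ValueError(f"{path}: no labels found")
    return np.asarray(labels)


def write_labels(path, labels) -> None:
    with open(path, "w") as fh:
        for lab in labels:
            fh.write(f"{lab}\n")


def write_trajectory(path, trajectory) -> None:
    with open(path, "w") as fh:
        fh.write("iteration\tobjective\n")
        for i, val in enumerate(trajectory):
            fh.write(f"{i}\t{val:.17g}\n")


@dataclass
class PipelineConfig:
    """Everything needed to run simulate-or-load -> fit -> cluster -> select."""

    out_dir: str
    input: str | None = None
    labels: str | None = None
    # synthetic generation (used when input is None)
    m: int = 300
    n: int = 150
    classes: int = 3
    noise_sd: float = 0.1
    outlier_fraction: float = 0.0
    # factorization
    k: int | None = None
    alpha: float = 1.0
    norm: str = "l21"
    manifold: str = "hypergraph"
    g: int = 5
    max_iter: int = 1000
    tol: float = 1e-6
    gamma: float = 1e-8
    # downstream
    n_clusters: int | None = None
    n_genes: int = 100
    seed: int = 0


@dataclass
class RunManifest:
    config: dict
    seed: int
    started: str
    finished: str = ""
    iterations: int = 0
    converged: bool = False
    outputs: dict = field(default_factory=dict)
    version: str = __version__
    notes: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Full pipeline; every output is written under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config),
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    true_labels = None
    if config.input is None:
        ds = generate(
            m=config.m,
            n=config.n,
            c=config.classes,
            noise_sd=config.noise_sd,
            outlier_fraction=config.outlier_fraction,
            seed=config.seed,
        )
        gene_ids = [f"gene{i}" for i in range(ds.X.shape[0])]
        sample_ids = [f"sample{j}" for j in range(ds.X.shape[1])]
        matrix = ExpressionMatrix(ds.X, gene_ids, sample_ids)
        write_expression_matrix(out / "X.tsv", matrix)
        write_labels(out / "labels.txt", ds.true_labels)
        manifest.outputs["X"] = str(out / "X.tsv")
        manifest.outputs["labels"] = str(out / "labels.txt")
        true_labels = ds.true_labels
    else:
        matrix = read_expression_matrix(config.input)
        if config.labels is not None:
            true_labels = read_labels(config.labels)
            if true_labels.shape[0] != matrix.shape[1]:
                raise ValueError(
                    "labels length does not match the number of samples"
                )

    n_classes = (
        np.unique(true_labels).size if true_labels is not None else None
    )
    k = config.k or n_classes or 2
    n_clusters = config.n_clusters or n_classes or k

    fit_cfg = FitConfig(
        k=k,
        alpha=config.alpha,
        norm=config.norm,
        manifold=config.manifold,
        g=config.g,
        max_iter=config.max_iter,
        tol=config.tol,
        gamma=config.gamma,
        seed=config.seed,
    )
    result = fit(matrix.values, fit_cfg)
    manifest.iterations = result.iterations_run
    manifest.converged = result.converged

    factor_ids = [f"factor{i}" for i in range(k)]
    write_matrix(out / "U.tsv", result.U, matrix.gene_ids, factor_ids)
    write_matrix(out / "V.tsv", result.V, factor_ids, matrix.sample_ids)
    write_trajectory(out / "trajectory.tsv", result.objective_trajectory)
    manifest.outputs["U"] = str(out / "U.tsv")
    manifest.outputs["V"] = str(out / "V.tsv")
    manifest.outputs["trajectory"] = str(out / "trajectory.tsv")

    pred = cluster_coefficients(result.V, n_clusters, seed=config.seed)
    write_labels(out / "labels_pred.txt", pred)
    manifest.outputs["labels_pred"] = str(out / "labels_pred.txt")

    if true_labels is not None:
        ev = evaluate_clustering(pred, true_labels)
        with open(out / "evaluation.json", "w") as fh:
            json.dump({"ac": ev.ac, "nmi": ev.nmi}, fh, indent=2)
        manifest.outputs["evaluation"] = str(out / "evaluation.json")
    else:
        manifest.notes.append("no ground-truth labels: evaluation skipped")

    ranking = score_genes(result.U, matrix.gene_ids)
    n_genes = min(config.n_genes, len(ranking.gene_ids))
    top = select_top(ranking, n_genes)
    with open(out / "gene_scores.tsv", "w") as fh:
        fh.write("gene_id\tscore\n")
        for gid, sc in zip(ranking.gene_ids, ranking.scores):
            fh.write(f"{gid}\t{sc:.17g}\n")
    write_labels(out / f"genes_top{n_genes}.txt", top)
    manifest.outputs["gene_scores"] = str(out / "gene_scores.tsv")
    manifest.outputs["genes_top"] = str(out / f"genes_top{n_genes}.txt")

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest
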