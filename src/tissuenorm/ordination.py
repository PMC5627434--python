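"""Classical principal coordinate analysis (PCoA) and variance screens.

PCoA (classical multidimensional scaling) embeds samples from a distance
matrix: Gower double-centering of -0.5 * d^2, eigendecomposition, and
coordinates formed by scaling eigenvectors by the square roots of the
non-negative eigenvalues.  With Euclidean input distances the embedding
reproduces the distances exactly, which is what makes it a faithful QC
view of sample structure; unlike correlation-based PCA it cannot hide
large mean shifts between samples.

The variance screen (:func:`most_variable_genes`) ranks genes by the
variance of log2(count + offset) across samples; it feeds the subgroup
merge assessment, which by convention looks at the most variable
autosomal genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import ExpressionExperiment


@dataclass
class OrdinationResult:
    """Output of a PCoA embedding.

    Attributes
    ----------
    coordinates
        samples-by-axes matrix of principal coordinates.
    eigenvalues
        All eigenvalues of the double-centered matrix, sorted
        non-increasing (negative ones possible for non-Euclidean input).
    variance_explained
        Fraction of (positive-eigenvalue) variance captured per retained
        axis.
    n_axes_for_90pct
        Smallest number of leading axes whose cumulative variance fraction
        reaches 0.90 — the conventional "how many components to inspect"
        rule of thumb.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    n_axes_for_90pct: int


def log_transform(matrix: np.ndarray, offset: float = 1.0) -> np.ndarray:
    """Elementwise log2(x + offset) of a non-negative matrix.

    ``offset=1.0`` is the default; ``offset=0.5`` gives the
    continuity-corrected variant.  Negative entries raise.
    """
    matrix = np.asarray(matrix, dtype=float)
    if offset <= 0:
        raise ValueError("offset must be positive")
    if np.any(matrix < 0):
        raise ValueError("log_transform requires non-negative entries")
    return np.log2(matrix + offset)


def euclidean_distances(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between the *columns* (samples)."""
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("euclidean_distances requires finite entries")
    return squareform(pdist(matrix.T, metric="euclidean"))


def pcoa(dist: np.ndarray, n_axes: int | None = None) -> OrdinationResult:
    """Classical PCoA of a symmetric zero-diagonal distance matrix.

    Negative eigenvalues (possible for non-Euclidean dissimilarities) are
    dropped from the coordinates and excluded from the variance-explained
    denominator, with a warning.  Axis signs are canonicalized so the
    largest-magnitude loading on each axis is positive, making results
    deterministic across eigensolvers.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist) < -1e-12) or np.any(dist < -1e-12):
        raise ValueError("distances must be non-negative")
    if n_axes is None:
        n_axes = n - 1
    if n_axes > n - 1:
        raise ValueError(f"n_axes={n_axes} exceeds n_samples-1={n - 1}")

    # Gower double centering of -1/2 d^2
    d2 = dist**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ d2 @ centerer
    b = (b + b.T) / 2.0  # symmetrize against round-off

    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]

    tol = 1e-8 * max(abs(eigval).max(), 1e-300) if eigval.size else 0.0
    if eigval.size and eigval.min() < -tol:
        warnings.warn(
            "negative PCoA eigenvalues dropped (non-Euclidean input?)",
            stacklevel=2,
        )

    positive = eigval > tol
    n_pos = int(positive.sum())
    k = min(n_axes, n_pos)
    coords = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))

    # canonical sign: force the largest-magnitude loading positive
    for ax in range(k):
        col = coords[:, ax]
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            coords[:, ax] = -col

    total = eigval[positive].sum()
    if total > 0:
        var_exp = np.maximum(eigval[:k], 0.0) / total
        cum = np.cumsum(np.maximum(eigval[:n_pos], 0.0)) / total
        n90 = int(np.searchsorted(cum, 0.90 - 1e-12) + 1)
    else:
        var_exp = np.zeros(k)
        n90 = 0
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eigval,
        variance_explained=var_exp,
        n_axes_for_90pct=n90,
    )


def most_variable_genes(
    expr: ExpressionExperiment,
    n: int = 1000,
    transform_offset: float = 1.0,
) -> list[str]:
    """Ids of the ``n`` genes with highest log-scale expression variance.

    Variance is the unbiased (n-1 denominator) sample variance of
    log2(count + offset) across samples, ranked descending; ties keep the
    input gene order (stable sort), so the output is deterministic.
    Returns min(n, n_genes) ids.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    logged = log_transform(expr.counts, transform_offset)
    variances = logged.var(axis=1, ddof=1) if expr.n_samples > 1 else np.zeros(
        expr.n_genes
    )
    order = np.argsort(-variances, kind="stable")
    return [expr.gene_ids[i] for i in order[: min(n, expr.n_genes)]]
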