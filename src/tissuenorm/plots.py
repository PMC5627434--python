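"""Static diagnostic plots: ordination scatter, per-sample density,
most-variable-gene heatmap.  File output only, no interactive GUI."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import ExpressionExperiment, subset
from .ordination import OrdinationResult, log_transform, most_variable_genes


def plot_ordination(
    result: OrdinationResult, labels, path, axes=(0, 1)
) -> None:
    """Scatter of two principal coordinates, colored by label."""
    coords = result.coordinates
    a, b = axes
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        sel = labels == lab
        ax.scatter(coords[sel, a], coords[sel, b], label=str(lab), s=18)
    ve = result.variance_explained
    ax.set_xlabel(f"PCo{a + 1} ({ve[a]:.0%})" if a < len(ve) else f"PCo{a + 1}")
    ax.set_ylabel(f"PCo{b + 1} ({ve[b]:.0%})" if b < len(ve) else f"PCo{b + 1}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_density(expr: ExpressionExperiment, path, offset: float = 1.0,
                 assay: str | None = None) -> None:
    """Per-sample density of log2 expression (raw counts or an assay)."""
    mat = expr.assays[assay] if assay else expr.counts
    logged = log_transform(np.asarray(mat), offset)
    fig, ax = plt.subplots(figsize=(5, 4))
    grid = np.linspace(logged.min(), logged.max(), 200)
    for j in range(logged.shape[1]):
        col = logged[:, j]
        # simple Gaussian KDE by hand-rolled bandwidth would be overkill;
        # a histogram-based curve is enough for a QC glance
        hist, edges = np.histogram(col, bins=40, density=True)
        centers = (edges[:-1] + edges[1:]) / 2
        ax.plot(centers, hist, alpha=0.4, lw=0.8)
    ax.set_xlabel("log2(expression + offset)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_top_gene_heatmap(
    expr: ExpressionExperiment, path, n: int = 15, offset: float = 1.0
) -> None:
    """Heatmap of the n most variable genes (log2 scale)."""
    genes = most_variable_genes(expr, n=n, transform_offset=offset)
    top = subset(expr, gene_ids=genes)
    logged = log_transform(top.counts, offset)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(logged, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(genes)))
    ax.set_yticklabels(genes, fontsize=6)
    ax.set_xlabel("samples")
    fig.colorbar(im, ax=ax, label="log2(count + offset)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
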