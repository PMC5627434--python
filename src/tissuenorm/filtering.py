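"""Gene-level filters: low-expression (tissue-aware / tissue-agnostic),
chromosome, missing-gene, and biotype tallies.

The low-expression rule keeps a gene iff it reaches a CPM threshold
(default 1 count per million) in at least ``min_samples`` samples, where
pass counts are pooled over **all** samples.  ``min_samples`` defaults to

* half the size of the smallest phenotype group when a group column is
  given ("tissue-aware" — a gene fully expressed in the smallest tissue
  can survive on that tissue's samples alone), or
* half of all samples otherwise ("tissue-agnostic").

``min_samples`` is kept as an exact real (possibly fractional, e.g. 7/2)
and compared with >= — no rounding.  Because a tissue-aware threshold is
never larger than the agnostic one, tissue-aware filtering always retains
a superset of the agnostic gene set; the difference is exactly the
tissue-specific genes an agnostic filter throws away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .core import ExpressionExperiment, normalize_chromosome, subset


@dataclass
class FilterResult:
    """Record of one filtering pass: what survived, what did not, and why."""

    retained_ids: list
    removed_ids: list
    rule: str
    cpm_threshold: Optional[float] = None
    min_samples: Optional[float] = None
    group_column: Optional[str] = None
    per_gene_pass_count: dict = field(default_factory=dict)


def cpm(counts: np.ndarray) -> np.ndarray:
    """Counts per million: counts / column library size * 1e6.

    Library sizes (column sums) are computed on the matrix as passed in,
    at call time.  A zero library size is an error naming the sample index.
    """
    counts = np.asarray(counts, dtype=float)
    libsize = counts.sum(axis=0)
    zero = np.nonzero(libsize == 0)[0]
    if zero.size:
        raise ValueError(f"zero library size for sample column(s) {zero.tolist()}")
    return counts / libsize * 1e6


def min_samples_tissue_aware(group_sizes: Mapping[str, int]) -> float:
    """Half the size of the smallest group, exactly (no rounding).

    This is the tissue-aware sample threshold: with a smallest group of 36
    samples, a gene must reach the CPM cutoff in at least 18 samples.
    """
    if not group_sizes:
        raise ValueError("empty group-size map")
    sizes = list(group_sizes.values())
    if min(sizes) < 1:
        raise ValueError("all group sizes must be >= 1")
    return min(sizes) / 2.0


def filter_low_genes(
    expr: ExpressionExperiment,
    group_column: Optional[str] = None,
    cpm_threshold: float = 1.0,
    min_samples: Optional[float] = None,
) -> tuple[ExpressionExperiment, FilterResult]:
    """Remove genes below the CPM threshold in too few samples.

    With ``group_column`` the threshold derives from the smallest group
    (tissue-aware); without it, from half the cohort (tissue-agnostic).
    An explicit ``min_samples`` overrides both.
    """
    if group_column is not None:
        groups = expr.sample_table[group_column]
        if groups.isna().any() or (groups.astype(str).str.len() == 0).any():
            raise ValueError(f"empty group label in column '{group_column}'")
        if min_samples is None:
            sizes = groups.value_counts().to_dict()
            min_samples = min_samples_tissue_aware(sizes)
        rule = "low_expression_tissue_aware"
    else:
        if min_samples is None:
            min_samples = expr.n_samples / 2.0
        rule = "low_expression_tissue_agnostic"
    if min_samples > expr.n_samples:
        warnings.warn(
            f"min_samples={min_samples} exceeds the {expr.n_samples} samples; "
            "every gene may be removed",
            stacklevel=2,
        )

    pass_counts = (cpm(expr.counts) >= cpm_threshold).sum(axis=1)
    keep = pass_counts >= min_samples
    gene_ids = expr.gene_ids
    result = FilterResult(
        retained_ids=list(gene_ids[keep]),
        removed_ids=list(gene_ids[~keep]),
        rule=rule,
        cpm_threshold=cpm_threshold,
        min_samples=float(min_samples),
        group_column=group_column,
        per_gene_pass_count={g: int(c) for g, c in zip(gene_ids, pass_counts)},
    )
    out = subset(expr, gene_ids=result.retained_ids)
    out.provenance_log[-1] = {
        **out.provenance_log[-1],
        "operation": "filter_low_genes",
        "parameters": {
            "rule": rule,
            "cpm_threshold": cpm_threshold,
            "min_samples": float(min_samples),
            "group_column": group_column,
            "n_removed": len(result.removed_ids),
        },
    }
    return out, result


def filter_genes_by_chromosome(
    expr: ExpressionExperiment,
    chromosomes: set,
    mode: str = "remove",
) -> tuple[ExpressionExperiment, FilterResult]:
    """Remove (or keep only) genes on the given chromosomes.

    Accepts "M" as an alias for "MT".
    """
    if mode not in ("remove", "keep"):
        raise ValueError("mode must be 'remove' or 'keep'")
    wanted = {normalize_chromosome(c) for c in chromosomes}
    on_chrom = expr.gene_table["chromosome"].map(normalize_chromosome).isin(wanted)
    keep = on_chrom if mode == "keep" else ~on_chrom
    gene_ids = expr.gene_ids
    result = FilterResult(
        retained_ids=list(gene_ids[keep.to_numpy()]),
        removed_ids=list(gene_ids[~keep.to_numpy()]),
        rule=f"chromosome_{mode}",
    )
    out = subset(expr, gene_ids=result.retained_ids)
    out.provenance_log[-1] = {
        **out.provenance_log[-1],
        "operation": "filter_genes_by_chromosome",
        "parameters": {"chromosomes": sorted(wanted), "mode": mode},
    }
    return out, result


def filter_missing_genes(
    expr: ExpressionExperiment,
) -> tuple[ExpressionExperiment, FilterResult]:
    """Remove genes with zero total count across all samples."""
    total = expr.counts.sum(axis=1)
    keep = total > 0
    gene_ids = expr.gene_ids
    result = FilterResult(
        retained_ids=list(gene_ids[keep]),
        removed_ids=list(gene_ids[~keep]),
        rule="missing",
    )
    out = subset(expr, gene_ids=result.retained_ids)
    out.provenance_log[-1] = {
        **out.provenance_log[-1],
        "operation": "filter_missing_genes",
        "parameters": {"n_removed": len(result.removed_ids)},
    }
    return out, result


def biotype_summary(expr: ExpressionExperiment) -> dict[str, tuple[int, float]]:
    """Tally gene biotypes: biotype -> (count, fraction of genes)."""
    counts = expr.gene_table["biotype"].value_counts()
    n = max(expr.n_genes, 1)
    return {b: (int(c), c / n) for b, c in counts.items()}
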