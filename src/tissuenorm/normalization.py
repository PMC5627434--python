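"""Quantile normalization, smooth (group-aware) quantile normalization,
and the reference-divergence RMSE diagnostic.

Plain quantile normalization forces every sample onto a single reference
distribution — the mean of the per-sample order statistics.  That is fine
when samples share one underlying expression distribution, but in a
multi-tissue study the pooled reference represents no tissue at all:
tissue-specific genes put a heavy spike at zero in some groups and not
others, and a global reference smears it across everything.

Smooth quantile normalization relaxes the single-distribution assumption
to "similar *within* each phenotype group".  At each quantile rank k it
blends the global reference q̄_k with the sample's group reference q̄_{g,k}:

    value(k, sample in group g) = w_k * q̄_k + (1 - w_k) * q̄_{g,k}

where the weight w_k measures how much of the total variance of the k-th
order statistic lies *between* groups:

    SST_k = Σ_j (Q(k,j) − q̄_k)²        (total)
    SSB_k = Σ_g n_g (q̄_{g,k} − q̄_k)²   (between groups)
    ŵ_k   = 1 − SSB_k / SST_k           (1 when SST_k = 0)

so quantiles where groups agree are normalized globally (w≈1) and
quantiles where they differ keep their group's own shape (w→0).  The raw
weight sequence is smoothed by a running median over a window of 5% of
the genes (configurable; window 1 disables smoothing) and clamped to
[0, 1].

Ties within a sample receive the mean of the target values over the tied
ranks — identical for all three normalizers; with count data the zero
spike makes the tie rule load-bearing for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionExperiment
from .ordination import log_transform


@dataclass
class QuantileReference:
    """Mean order-statistic reference distribution (one value per rank)."""

    values: np.ndarray  # ascending, length = n_genes
    scope: str  # "global" or "group:<name>"


@dataclass
class NormalizationResult:
    normalized: np.ndarray
    method: str  # qsmooth | quantile_global | quantile_per_group
    global_reference: QuantileReference
    group_references: dict = field(default_factory=dict)
    weights: Optional[np.ndarray] = None  # per-rank w_k, qsmooth only
    group_column: Optional[str] = None


def _assign_by_rank(column: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Map a sample's values onto ``target`` (ascending) via its ranks.

    Tied raw values all receive the mean of the target values at the tied
    ranks, so equal inputs stay equal and the mapping is deterministic.
    """
    order = np.argsort(column, kind="mergesort")
    out = np.empty_like(target, dtype=float)
    out[order] = target
    sorted_vals = column[order]
    # average target over runs of tied raw values
    boundaries = np.nonzero(np.diff(sorted_vals) != 0)[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(column)]))
    for s, e in zip(starts, ends):
        if e - s > 1:
            out[order[s:e]] = target[s:e].mean()
    return out


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running median; the window shrinks at the edges."""
    if window <= 1:
        return values.copy()
    return (
        pd.Series(values)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def quantile_normalize(matrix: np.ndarray) -> NormalizationResult:
    """Full quantile normalization onto the mean order-statistic reference.

    Every sample's value at rank k is replaced by the mean, over samples,
    of the k-th order statistic; ties averaged (see module docstring).
    A single-sample matrix is returned unchanged with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_samples = matrix.shape
    sorted_cols = np.sort(matrix, axis=0)
    reference = sorted_cols.mean(axis=1)
    if n_samples < 2:
        warnings.warn("single sample: quantile normalization is the identity",
                      stacklevel=2)
        return NormalizationResult(
            normalized=matrix.copy(),
            method="quantile_global",
            global_reference=QuantileReference(reference, "global"),
        )
    normalized = np.empty_like(matrix)
    for j in range(n_samples):
        normalized[:, j] = _assign_by_rank(matrix[:, j], reference)
    return NormalizationResult(
        normalized=normalized,
        method="quantile_global",
        global_reference=QuantileReference(reference, "global"),
    )


def _group_indices(groups: Sequence) -> dict:
    groups = np.asarray(groups)
    if groups.dtype == object and any(g is None for g in groups):
        raise ValueError("group label missing for a sample")
    if pd.isna(groups).any():
        raise ValueError("group label missing for a sample")
    out: dict = {}
    for j, g in enumerate(groups):
        out.setdefault(g, []).append(j)
    for g, idx in out.items():
        if not idx:
            raise ValueError(f"empty group '{g}'")
    return {g: np.array(idx) for g, idx in out.items()}


def qsmooth_normalize(
    matrix: np.ndarray,
    groups: Sequence,
    window_fraction: float = 0.05,
    weight_override: Optional[float] = None,
) -> NormalizationResult:
    """Smooth quantile normalization with per-group references.

    Parameters
    ----------
    matrix
        Genes-by-samples expression matrix.
    groups
        Per-sample phenotype-group labels (one per column).
    window_fraction
        Running-median window for the weight sequence, as a fraction of
        the number of genes (rounded, forced odd; 0 or a window of 1
        disables smoothing).
    weight_override
        Force every w_k to this constant (0 reduces the method to
        per-group quantile normalization, 1 to global); intended for
        equivalence checks.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_samples = matrix.shape
    if len(groups) != n_samples:
        raise ValueError("groups length must equal the number of samples")
    idx = _group_indices(groups)

    sorted_cols = np.sort(matrix, axis=0)  # Q(k, j)
    qbar = sorted_cols.mean(axis=1)
    group_refs = {g: sorted_cols[:, jx].mean(axis=1) for g, jx in idx.items()}

    if weight_override is not None:
        w = np.full(n_genes, float(weight_override))
    else:
        sst = ((sorted_cols - qbar[:, None]) ** 2).sum(axis=1)
        ssb = np.zeros(n_genes)
        for g, jx in idx.items():
            ssb += len(jx) * (group_refs[g] - qbar) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            raw_w = np.where(sst > 0, 1.0 - ssb / np.where(sst > 0, sst, 1.0), 1.0)
        window = int(round(window_fraction * n_genes))
        if window % 2 == 0:
            window += 1
        w = np.clip(_running_median(raw_w, window), 0.0, 1.0)

    normalized = np.empty_like(matrix)
    for g, jx in idx.items():
        # the blend of two ascending references can dip where w_k varies;
        # sorting restores the quantile-function (non-decreasing) contract
        # and is a no-op whenever the blend is already monotone
        target = np.sort(w * qbar + (1.0 - w) * group_refs[g])
        for j in jx:
            normalized[:, j] = _assign_by_rank(matrix[:, j], target)
    return NormalizationResult(
        normalized=normalized,
        method="qsmooth",
        global_reference=QuantileReference(qbar, "global"),
        group_references={
            g: QuantileReference(ref, f"group:{g}") for g, ref in group_refs.items()
        },
        weights=w,
    )


def quantile_normalize_per_group(
    matrix: np.ndarray, groups: Sequence
) -> NormalizationResult:
    """Full quantile normalization run independently within each group.

    Singleton groups pass through unchanged (with a warning): one sample
    defines no within-group reference beyond itself.
    """
    matrix = np.asarray(matrix, dtype=float)
    idx = _group_indices(groups)
    normalized = np.empty_like(matrix)
    group_refs = {}
    for g, jx in idx.items():
        block = matrix[:, jx]
        if len(jx) < 2:
            warnings.warn(f"group '{g}' has a single sample; left unchanged",
                          stacklevel=2)
            normalized[:, jx] = block
            group_refs[g] = QuantileReference(np.sort(block[:, 0]), f"group:{g}")
            continue
        res = quantile_normalize(block)
        normalized[:, jx] = res.normalized
        group_refs[g] = QuantileReference(res.global_reference.values, f"group:{g}")
    global_ref = QuantileReference(np.sort(matrix, axis=0).mean(axis=1), "global")
    return NormalizationResult(
        normalized=normalized,
        method="quantile_per_group",
        global_reference=global_ref,
        group_references=group_refs,
    )


def normalize_tissue_aware(
    expr: ExpressionExperiment,
    group_column: str = "merged_group",
    method: str = "qsmooth",
    window_fraction: float = 0.05,
) -> ExpressionExperiment:
    """Add a ``"normalized"`` assay computed from the raw counts.

    ``method`` is ``"qsmooth"`` (smooth quantile normalization) or
    ``"quantile_per_group"`` (full quantile normalization within each
    group).  Raw counts are preserved; re-running recomputes the assay
    from raw, so the call is idempotent.
    """
    groups = expr.sample_table[group_column]
    if groups.isna().any() or (groups.astype(str).str.len() == 0).any():
        raise ValueError(f"group column '{group_column}' is not fully populated")
    if method == "qsmooth":
        res = qsmooth_normalize(expr.counts, groups.to_numpy(), window_fraction)
    elif method == "quantile_per_group":
        res = quantile_normalize_per_group(expr.counts, groups.to_numpy())
    else:
        raise ValueError(f"unknown method '{method}'")
    out = expr.copy()
    out.assays["normalized"] = res.normalized
    out.log(
        "normalize_tissue_aware",
        method=method,
        group_column=group_column,
        window_fraction=window_fraction if method == "qsmooth" else None,
        n_groups=int(groups.nunique()),
    )
    return out


def reference_rmse(
    matrix: np.ndarray,
    groups: Optional[Sequence] = None,
    reference_scope: str = "global",
    transform_offset: float = 1.0,
) -> np.ndarray:
    """Per-sample RMSE between log quantiles and a reference's log quantiles.

    For sample j, RMSE_j = sqrt(mean_k (log2(Q(k,j)+offset) −
    log2(ref(k)+offset))²), with ref either the global mean-quantile
    reference or the sample's group reference, both computed on raw
    quantiles.  Large global-scope RMSEs relative to group scope indicate
    the single-reference assumption is failing for these samples.
    """
    matrix = np.asarray(matrix, dtype=float)
    if reference_scope not in ("global", "group"):
        raise ValueError("reference_scope must be 'global' or 'group'")
    sorted_cols = np.sort(matrix, axis=0)
    log_q = log_transform(sorted_cols, transform_offset)
    if reference_scope == "global":
        ref_log = log_transform(sorted_cols.mean(axis=1), transform_offset)
        diffs = log_q - ref_log[:, None]
    else:
        if groups is None:
            raise ValueError("groups required for scope='group'")
        idx = _group_indices(groups)
        diffs = np.empty_like(log_q)
        for g, jx in idx.items():
            ref_log = log_transform(
                sorted_cols[:, jx].mean(axis=1), transform_offset
            )
            diffs[:, jx] = log_q[:, jx] - ref_log[:, None]
    return np.sqrt((diffs**2).mean(axis=0))
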