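"""Sample-annotation QC: sex-misannotation screening and subgroup merge
assessment, both built on PCoA ordination.

Sex screening exploits Y-chromosome expression: genetically male samples
express Y-linked genes, others essentially do not, so a PCoA of
log-transformed Y-gene counts splits samples into two tight clusters.
A sample whose recorded sex disagrees with its cluster's majority label
is flagged as a likely misannotation.

Merge assessment asks whether sub-sites of one body site are
transcriptionally distinguishable: restrict to the site's samples and the
most variable autosomal genes (sex and mitochondrial chromosomes
excluded), embed with PCoA, and score the sub-site labels with the mean
silhouette in the first-two-axes plane.  Low separation recommends
merging the sub-sites into one analysis group; high separation recommends
keeping them apart.  The original calls in this workflow were visual;
the explicit decision rules here (2-means on axis 1, silhouette
thresholds) make the same judgement automatable while always returning
the ordination for human inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import ExpressionExperiment, normalize_chromosome, subset
from .ordination import (
    OrdinationResult,
    euclidean_distances,
    log_transform,
    most_variable_genes,
    pcoa,
)

#: Silhouette below this => sub-sites look like one population: merge.
MERGE_THRESHOLD_LOW = 0.25
#: Silhouette above this => clearly separate populations: keep separate.
MERGE_THRESHOLD_HIGH = 0.5


@dataclass
class MisannotationReport:
    """Outcome of the chromosome-based annotation screen."""

    records: pd.DataFrame  # sample_id, annotated_label, assigned_cluster,
    #                        cluster_majority_label, concordant
    flagged_ids: list
    ordination: Optional[OrdinationResult]
    genes_used: list
    warning: Optional[str] = None


@dataclass
class MergeAssessment:
    major_site: str
    ordination: OrdinationResult
    subgroup_labels: np.ndarray
    separation_score: float  # mean silhouette, in [-1, 1]
    recommendation: str  # merge | keep_separate | inspect
    genes_used: list = field(default_factory=list)


def check_misannotation(
    expr: ExpressionExperiment,
    label_column: str = "sex",
    chromosome: str = "Y",
    transform_offset: float = 1.0,
    n_axes: int = 2,
    cluster_on_90pct_axes: bool = False,
) -> MisannotationReport:
    """Flag samples whose recorded label contradicts their expression.

    Subsets to genes on ``chromosome`` (default Y), log2-transforms,
    embeds with PCoA on Euclidean distances, splits samples into two
    clusters by k-means (k=2, 10 restarts, fixed seed) on the first axis
    (or on the axes covering 90% of variance when
    ``cluster_on_90pct_axes``), assigns each cluster the majority
    annotated label, and flags disagreements.  Samples labelled
    "unknown" are clustered but never flagged — there is no annotation to
    contradict.
    """
    chrom = normalize_chromosome(chromosome)
    on_chrom = expr.gene_table["chromosome"].map(normalize_chromosome) == chrom
    gene_ids = list(expr.gene_ids[on_chrom.to_numpy()])
    if len(gene_ids) < 2:
        raise ValueError(
            f"cannot screen without marker genes: found {len(gene_ids)} gene(s) "
            f"on chromosome '{chromosome}'"
        )
    if expr.n_samples < 4:
        raise ValueError("need at least 4 samples to screen")
    labels = expr.sample_table[label_column].astype(str)
    observed = sorted(set(labels) - {"unknown"})
    if len(observed) != 2:
        raise ValueError(
            f"label column '{label_column}' must have exactly 2 observed "
            f"levels besides 'unknown', found {observed}"
        )

    marker = subset(expr, gene_ids=gene_ids)
    logged = log_transform(marker.counts, transform_offset)
    dist = euclidean_distances(logged)

    sample_ids = expr.sample_ids
    if dist.max() < 1e-10:
        msg = "all samples are identical on the marker genes; nothing to flag"
        warnings.warn(msg, stacklevel=2)
        records = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "annotated_label": labels.to_numpy(),
                "assigned_cluster": 0,
                "cluster_majority_label": "unknown",
                "concordant": True,
            }
        )
        return MisannotationReport(records, [], None, gene_ids, warning=msg)

    ordination = pcoa(dist, n_axes=min(n_axes, expr.n_samples - 1))
    if cluster_on_90pct_axes:
        k = max(1, min(ordination.n_axes_for_90pct, ordination.coordinates.shape[1]))
    else:
        k = 1
    features = ordination.coordinates[:, :k]
    km = KMeans(n_clusters=2, n_init=10, random_state=0)
    clusters = km.fit_predict(features)

    majority = {}
    for c in (0, 1):
        known = labels[(clusters == c) & (labels != "unknown").to_numpy()]
        majority[c] = known.mode().iloc[0] if len(known) else "unknown"

    concordant = np.array(
        [
            lab == "unknown" or majority[c] == "unknown" or lab == majority[c]
            for lab, c in zip(labels, clusters)
        ]
    )
    records = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "annotated_label": labels.to_numpy(),
            "assigned_cluster": clusters,
            "cluster_majority_label": [majority[c] for c in clusters],
            "concordant": concordant,
        }
    )
    flagged = list(sample_ids[~concordant])
    return MisannotationReport(records, flagged, ordination, gene_ids)


def assess_merge(
    expr: ExpressionExperiment,
    major_site: str,
    n_top_genes: int = 1000,
    exclude_chromosomes: frozenset = frozenset({"X", "Y", "MT"}),
    transform_offset: float = 1.0,
    low_threshold: float = MERGE_THRESHOLD_LOW,
    high_threshold: float = MERGE_THRESHOLD_HIGH,
) -> MergeAssessment:
    """Score how separable the sub-sites of one major site are.

    Restricts to the site's samples and autosomal genes, ranks the
    ``n_top_genes`` most variable genes on the log2 scale, embeds with
    PCoA, and computes the mean silhouette of the sub-site labels in the
    first-two-axes plane.  Recommendation: ``merge`` below
    ``low_threshold``, ``keep_separate`` above ``high_threshold``,
    ``inspect`` in between.
    """
    in_site = expr.sample_table["major_site"] == major_site
    if not in_site.any():
        raise ValueError(f"no samples with major_site '{major_site}'")
    site = subset(expr, sample_ids=list(expr.sample_ids[in_site.to_numpy()]))
    sub_sites = site.sample_table["sub_site"].to_numpy()
    levels, level_counts = np.unique(sub_sites, return_counts=True)
    if len(levels) < 2:
        raise ValueError(
            f"nothing to assess: major_site '{major_site}' has a single sub_site"
        )
    if level_counts.min() < 3:
        raise ValueError("need at least 3 samples per sub_site")

    excluded = {normalize_chromosome(c) for c in exclude_chromosomes}
    autosomal = ~site.gene_table["chromosome"].map(normalize_chromosome).isin(
        excluded
    )
    site = subset(site, gene_ids=list(site.gene_ids[autosomal.to_numpy()]))
    genes = most_variable_genes(site, n=n_top_genes, transform_offset=transform_offset)
    top = subset(site, gene_ids=genes)

    logged = log_transform(top.counts, transform_offset)
    dist = euclidean_distances(logged)
    ordination = pcoa(dist, n_axes=min(10, top.n_samples - 1))
    plane = ordination.coordinates[:, : min(2, ordination.coordinates.shape[1])]
    score = float(silhouette_score(plane, sub_sites))

    if score < low_threshold:
        recommendation = "merge"
    elif score > high_threshold:
        recommendation = "keep_separate"
    else:
        recommendation = "inspect"
    return MergeAssessment(
        major_site=major_site,
        ordination=ordination,
        subgroup_labels=sub_sites,
        separation_score=score,
        recommendation=recommendation,
        genes_used=genes,
    )


def apply_merge(
    expr: ExpressionExperiment, merge_map: Mapping[str, str]
) -> ExpressionExperiment:
    """Fill ``merged_group`` from a sub_site -> group mapping.

    Counts are untouched.  Every sub_site present in the experiment must
    appear in the map; unmapped sub_sites raise with their names listed.
    """
    sub_sites = expr.sample_table["sub_site"]
    unmapped = sorted(set(sub_sites) - set(merge_map))
    if unmapped:
        raise ValueError(f"sub_site(s) missing from merge map: {unmapped[:10]}")
    out = expr.copy()
    out.sample_table["merged_group"] = sub_sites.map(merge_map).to_numpy()
    out.log(
        "apply_merge",
        n_groups=int(out.sample_table["merged_group"].nunique()),
    )
    return out


def remove_flagged_samples(
    expr: ExpressionExperiment, report: MisannotationReport
) -> ExpressionExperiment:
    """Drop the samples a misannotation screen flagged."""
    keep = [s for s in expr.sample_ids if s not in set(report.flagged_ids)]
    if not keep:
        warnings.warn("every sample was flagged; result has no samples",
                      stacklevel=2)
    out = subset(expr, sample_ids=keep)
    out.provenance_log[-1] = {
        **out.provenance_log[-1],
        "operation": "remove_flagged_samples",
        "parameters": {"n_removed": expr.n_samples - len(keep)},
    }
    return out


def load_gtex_merge_map() -> pd.DataFrame:
    """Bundled GTEx v6 sub-site -> merged-group table (49 sub-sites,
    38 merged groups) with per-group sample sizes."""
    with resources.files("tissuenorm.data").joinpath("gtex_merge_map.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh, sep="\t")


def gtex_group_sizes() -> dict[str, int]:
    """Merged-group sample sizes from the bundled GTEx v6 table."""
    table = load_gtex_merge_map()
    sizes = table.drop_duplicates("merged_group").set_index("merged_group")[
        "group_sample_size"
    ]
    return {g: int(n) for g, n in sizes.items()}
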