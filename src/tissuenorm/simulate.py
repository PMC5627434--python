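"""Synthetic multi-group RNA-seq count experiments with known truth.

The generator emulates the data properties every pipeline stage is built
around, at desk scale:

* several phenotype groups ("tissues"), each with its own set of
  group-specific genes that are well expressed within the group and
  near-zero outside it — producing the zero spike that pools across
  groups and defeats global references;
* negative-binomial counts (variance = mu + dispersion * mu^2) with
  per-sample library-size variation;
* Y-chromosome marker genes expressed only in genetically male samples;
* optionally, samples whose *recorded* sex is flipped while their
  expression profile is untouched — planted misannotations with known
  ids for recovery tests.

Determinism: one master seed spawns a counter-based substream per sample
(and one for gene-level parameters), so the output does not depend on
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionExperiment


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated experiment."""

    seed: int
    group_of: dict  # sample_id -> group
    true_sex: dict  # sample_id -> male/female
    injected_misannotations: list
    tissue_specific_genes: dict  # group -> set of gene ids
    y_genes: set
    nb_mean: np.ndarray  # genes-by-groups expected means (pre library size)
    nb_dispersion: float
    library_size_range: tuple
    shifted_genes: set = field(default_factory=set)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative binomial with variance mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_experiment(
    n_groups: int = 3,
    samples_per_group: int = 10,
    n_genes: int = 500,
    tissue_specific_fraction: float = 0.1,
    y_gene_count: int = 20,
    misannotation_rate: float = 0.0,
    group_shift_log2: float = 2.0,
    nb_dispersion: float = 0.5,
    library_size_range: tuple = (0.7, 1.3),
    outside_group_mean: float = 0.05,
    y_gene_mean: float = 60.0,
    seed: int = 0,
) -> tuple[ExpressionExperiment, SimulationTruth]:
    """Simulate a multi-group count experiment with planted structure.

    Baseline gene means are log-normal; each group's specific genes are
    shifted up by ``group_shift_log2`` (log2 units) within the group and
    set near zero (mean ``outside_group_mean``) elsewhere.  Y-marker
    genes are expressed (mean ``y_gene_mean``) only in genetically male
    samples.  ``misannotation_rate`` of samples get their *recorded* sex
    flipped, and those ids are listed in the returned truth.  Fully
    deterministic given ``seed``.
    """
    if min(n_groups, samples_per_group, n_genes) < 1:
        raise ValueError("all sizes must be >= 1")
    if not (0 <= tissue_specific_fraction <= 1 and 0 <= misannotation_rate <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if y_gene_count > n_genes:
        raise ValueError("y_gene_count exceeds n_genes")

    rng_genes = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    n_samples = n_groups * samples_per_group
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    groups = [f"site{g}" for g in range(n_groups)]

    # gene annotation: Y markers first, the rest autosomal
    chromosomes = np.array(
        ["Y"] * y_gene_count
        + list(
            rng_genes.choice([str(c) for c in range(1, 23)], n_genes - y_gene_count)
        )
    )
    biotypes = rng_genes.choice(
        ["protein_coding", "pseudogene", "lincRNA"],
        n_genes,
        p=[0.6, 0.2, 0.2],
    )

    baseline = rng_genes.lognormal(mean=2.0, sigma=1.0, size=n_genes)

    n_specific = int(round(tissue_specific_fraction * n_genes))
    autosomal_pool = np.arange(y_gene_count, n_genes)
    specific_idx = rng_genes.choice(
        autosomal_pool, size=min(n_specific, len(autosomal_pool)), replace=False
    )
    specific_of_group = {
        g: specific_idx[i::n_groups] for i, g in enumerate(groups)
    }

    # genes-by-groups expected means (before library-size variation)
    nb_mean = np.tile(baseline[:, None], (1, n_groups))
    for gi, g in enumerate(groups):
        others = [j for j in range(n_groups) if j != gi]
        idx = specific_of_group[g]
        nb_mean[idx, gi] = baseline[idx] * 2.0**group_shift_log2
        for j in others:
            nb_mean[idx, j] = outside_group_mean
    nb_mean[:y_gene_count, :] = 0.0  # Y genes handled per-sample by sex

    sample_ids = [f"s{j:04d}" for j in range(n_samples)]
    group_of = {
        sid: groups[j // samples_per_group] for j, sid in enumerate(sample_ids)
    }
    true_sex = {
        sid: ("male" if j % 2 == 0 else "female")
        for j, sid in enumerate(sample_ids)
    }

    counts = np.zeros((n_genes, n_samples))
    lib_lo, lib_hi = library_size_range
    for j, sid in enumerate(sample_ids):
        rng_j = np.random.default_rng(np.random.SeedSequence([seed, 1, j]))
        lib_factor = rng_j.uniform(lib_lo, lib_hi)
        gi = groups.index(group_of[sid])
        mean_j = nb_mean[:, gi].copy()
        if true_sex[sid] == "male":
            mean_j[:y_gene_count] = y_gene_mean
        else:
            mean_j[:y_gene_count] = outside_group_mean
        counts[:, j] = _nb_draw(rng_j, mean_j * lib_factor, nb_dispersion)

    n_flip = int(round(misannotation_rate * n_samples))
    rng_flip = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    flipped = sorted(
        rng_flip.choice(sample_ids, size=n_flip, replace=False).tolist()
    )
    recorded_sex = {
        sid: (
            {"male": "female", "female": "male"}[true_sex[sid]]
            if sid in flipped
            else true_sex[sid]
        )
        for sid in sample_ids
    }

    gene_table = pd.DataFrame(
        {"gene_id": gene_ids, "chromosome": chromosomes, "biotype": biotypes}
    )
    sample_table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": [f"d{j:04d}" for j in range(n_samples)],
            "sex": [recorded_sex[s] for s in sample_ids],
            "major_site": [group_of[s] for s in sample_ids],
            "sub_site": [group_of[s] for s in sample_ids],
        }
    )
    expr = ExpressionExperiment(counts, gene_table, sample_table)
    expr.log(
        "simulate_experiment",
        seed=seed,
        n_groups=n_groups,
        samples_per_group=samples_per_group,
        n_genes=n_genes,
        misannotation_rate=misannotation_rate,
    )
    truth = SimulationTruth(
        seed=seed,
        group_of=group_of,
        true_sex=true_sex,
        injected_misannotations=flipped,
        tissue_specific_genes={
            g: {gene_ids[i] for i in idx} for g, idx in specific_of_group.items()
        },
        y_genes=set(gene_ids[:y_gene_count]),
        nb_mean=nb_mean,
        nb_dispersion=nb_dispersion,
        library_size_range=library_size_range,
    )
    return expr, truth


def simulate_mergeable_subsites(
    shift_log2: float,
    samples_per_subsite: int = 12,
    n_genes: int = 400,
    shifted_fraction: float = 0.3,
    nb_dispersion: float = 0.3,
    library_size_range: tuple = (0.8, 1.2),
    seed: int = 0,
) -> tuple[ExpressionExperiment, SimulationTruth]:
    """Two sub-sites of one major site, separated by a planted mean shift.

    ``shift_log2 = 0`` makes the sub-sites identically distributed (the
    mergeable case); a large shift in ``shifted_fraction`` of genes makes
    them clearly separable.  The shifted gene set is recorded in the
    truth.
    """
    if shift_log2 < 0:
        raise ValueError("shift_log2 must be >= 0")
    rng_genes = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    n_samples = 2 * samples_per_subsite
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    baseline = rng_genes.lognormal(mean=2.5, sigma=1.0, size=n_genes)
    n_shift = int(round(shifted_fraction * n_genes))
    shifted_idx = rng_genes.choice(n_genes, size=n_shift, replace=False)

    mean_a = baseline.copy()
    mean_b = baseline.copy()
    mean_b[shifted_idx] = baseline[shifted_idx] * 2.0**shift_log2

    sample_ids = [f"s{j:04d}" for j in range(n_samples)]
    sub_site_of = {
        sid: ("siteA" if j < samples_per_subsite else "siteB")
        for j, sid in enumerate(sample_ids)
    }
    counts = np.zeros((n_genes, n_samples))
    lib_lo, lib_hi = library_size_range
    for j, sid in enumerate(sample_ids):
        rng_j = np.random.default_rng(np.random.SeedSequence([seed, 11, j]))
        lib_factor = rng_j.uniform(lib_lo, lib_hi)
        mean_j = mean_a if sub_site_of[sid] == "siteA" else mean_b
        counts[:, j] = _nb_draw(rng_j, mean_j * lib_factor, nb_dispersion)

    gene_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": rng_genes.choice(
                [str(c) for c in range(1, 23)], n_genes
            ),
            "biotype": ["protein_coding"] * n_genes,
        }
    )
    sample_table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": [f"d{j:04d}" for j in range(n_samples)],
            "sex": ["unknown"] * n_samples,
            "major_site": ["major"] * n_samples,
            "sub_site": [sub_site_of[s] for s in sample_ids],
        }
    )
    expr = ExpressionExperiment(counts, gene_table, sample_table)
    expr.log(
        "simulate_mergeable_subsites",
        seed=seed,
        shift_log2=shift_log2,
        shifted_fraction=shifted_fraction,
    )
    nb_mean = np.column_stack([mean_a, mean_b])
    truth = SimulationTruth(
        seed=seed,
        group_of=sub_site_of,
        true_sex={s: "unknown" for s in sample_ids},
        injected_misannotations=[],
        tissue_specific_genes={},
        y_genes=set(),
        nb_mean=nb_mean,
        nb_dispersion=nb_dispersion,
        library_size_range=library_size_range,
        shifted_genes={gene_ids[i] for i in shifted_idx},
    )
    return expr, truth
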