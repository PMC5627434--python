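"""Tissue-aware versus tissue-agnostic low-expression filtering.

The tissue-aware rule keeps a gene reaching 1 CPM in at least half as
many samples as the smallest group has — so a gene expressed only in one
small tissue survives.  The agnostic rule (half of all samples) removes
exactly those genes."""

from tissuenorm import (
    filter_low_genes,
    gtex_group_sizes,
    min_samples_tissue_aware,
    simulate_experiment,
)

sizes = gtex_group_sizes()
print(f"bundled tissue table: {len(sizes)} merged groups, "
      f"{sum(sizes.values())} samples")
print(f"smallest group: {min(sizes, key=sizes.get)} ({min(sizes.values())}) "
      f"-> tissue-aware threshold {min_samples_tissue_aware(sizes)} samples")

expr, truth = simulate_experiment(
    n_groups=3, samples_per_group=10, n_genes=500,
    tissue_specific_fraction=0.2, seed=4,
)
expr.sample_table["merged_group"] = expr.sample_table["sub_site"]
_, aware = filter_low_genes(expr, group_column="merged_group")
_, agnostic = filter_low_genes(expr, group_column=None)
print(f"tissue-aware:    kept {len(aware.retained_ids)} of {expr.n_genes} "
      f"(min_samples={aware.min_samples})")
print(f"tissue-agnostic: kept {len(agnostic.retained_ids)} of {expr.n_genes} "
      f"(min_samples={agnostic.min_samples})")
specific = set().union(*truth.tissue_specific_genes.values())
rescued = specific & set(aware.retained_ids) & set(agnostic.removed_ids)
print(f"planted group-specific genes rescued only by the aware rule: "
      f"{len(rescued)}")
# The aware rule keeps a superset of the agnostic gene set; the difference
# is dominated by the planted group-specific genes.
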