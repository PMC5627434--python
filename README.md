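# tissuenorm

Preprocessing for large, heterogeneous bulk RNA-seq studies: sample-annotation
QC, subgroup merge assessment, tissue-aware gene filtering, and group-aware
(smooth) quantile normalization, with a synthetic multi-tissue count simulator
for ground-truth testing.

Multi-tissue expression studies break the assumptions behind the standard
small-study toolkit.  Each tissue expresses its own set of tissue-specific
genes, so pooled count distributions grow a spike at zero as tissues are
added; a filter or normalizer that treats all samples as draws from one
distribution either throws those genes away or distorts them.  `tissuenorm`
is for analysts assembling a cross-tissue (or any multi-group) count matrix
who need the preprocessing to respect group structure.

## What it computes

The pipeline runs four stages on a genes-by-samples count matrix with gene
and sample annotation:

1. **Annotation QC** — embed samples with classical PCoA (Gower
   double-centering of −½d² of Euclidean distances) on log₂ Y-chromosome
   counts; 2-means on the first axis splits the sexes, and a sample whose
   recorded sex disagrees with its cluster's majority is flagged as a likely
   misannotation.
2. **Merge assessment** — for sub-sites of one body site: take the 1000 most
   variable autosomal genes (unbiased variance of log₂(count+1)), PCoA, and
   the mean silhouette *s* of sub-site labels in the first two axes.
   *s* < 0.25 ⇒ merge, *s* > 0.5 ⇒ keep separate, else inspect.
3. **Tissue-aware filtering** — keep gene *i* iff
   #{j : CPM_ij ≥ 1} ≥ n_min/2, where n_min is the size of the smallest
   merged group (18 for the bundled 38-tissue table whose smallest group has
   36 samples).  The agnostic variant uses half of all samples instead and
   provably removes small-group-specific genes the aware rule keeps.
4. **Smooth quantile normalization (qsmooth-style)** — with per-sample order
   statistics Q(k,j), global reference q̄_k = mean_j Q(k,j) and group
   references q̄_{g,k}, each sample in group g receives at rank k

   w_k·q̄_k + (1−w_k)·q̄_{g,k},  w_k = median-smoothed (1 − SSB_k/SST_k),

   where SSB_k/SST_k is the between-group share of the k-th quantile's
   variance.  w_k→1 normalizes globally where groups agree; w_k→0 preserves
   each group's distribution where they diverge.  Full per-group quantile
   normalization and the per-sample RMSE of log quantiles against a
   global/group reference (the diagnostic motivating the group-aware choice)
   are included.

## Worked example

`examples/` contains one narrative script per capability.  The sex screen
(`examples/02_sex_misannotation_screen.py`) simulates 40 samples with 10% of
recorded sexes flipped and prints:

```
samples screened: 40
injected swaps:   ['s0009', 's0018', 's0032', 's0033']
flagged samples:  ['s0009', 's0018', 's0032', 's0033']
variance on first axis: 92.9%
```

The flagged set equals the planted swaps — every misannotation recovered with
no false positives — and the first principal coordinate carries 92.9% of the
Y-expression variance, which is why clustering on that single axis suffices.
The filtering example (`examples/04_tissue_aware_filtering.py`) shows the two
filter rules disagreeing exactly on the planted group-specific genes:

```
tissue-aware:    kept 499 of 500 (min_samples=5.0)
tissue-agnostic: kept 391 of 500 (min_samples=15.0)
planted group-specific genes rescued only by the aware rule: 100
```

The same stages are scriptable from the shell:

```bash
tissuenorm simulate --groups 3 --samples-per-group 12 --genes 1000 --seed 7 --out sim/
tissuenorm qc sex-check --counts sim/counts.tsv --samples sim/samples.tsv \
    --genes sim/genes.tsv --out report.tsv
tissuenorm run --counts sim/counts.tsv --samples sim/samples.tsv \
    --genes sim/genes.tsv --out-dir out/
```

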