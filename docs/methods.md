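# Methods

This note documents the models and procedures `tissuenorm` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices that make results reproducible.

## The problem setting

The input is a genes-by-samples matrix of raw read counts from a study whose
samples fall into phenotype groups (tissues, conditions) with genuinely
different expression programs.  Two features of such data drive every design
choice here:

* **Tissue-specific genes.** A gene can be strongly expressed in one group
  and absent elsewhere.  Pooled across groups, its counts form a spike at
  zero plus a well-expressed tail; pooled summary statistics (a global CPM
  filter, a global quantile reference) misrepresent both parts.
* **Annotation error.** At cohort scale, a small fraction of samples carry
  wrong metadata.  Sex is the one label that expression can check almost for
  free, via Y-chromosome genes, and it serves as a canary for overall
  annotation quality.

## Ordination

Sample structure is assessed with classical principal coordinate analysis:
given a distance matrix *d*, form B = −½·J·d²·J with J the centering matrix,
eigendecompose, and scale eigenvectors by √λ.  With Euclidean distances the
embedding reproduces the input distances exactly (verified to 1e−8 in the
tests), which makes inter-sample distance directly readable from the plot —
the property that motivates PCoA over correlation-based PCA for QC, since a
large mean shift moves a sample visibly instead of vanishing into a
correlation.

Numerical choices: eigenvalues below 1e−8 of the spectral radius are treated
as zero; negative eigenvalues (impossible for Euclidean input up to
round-off, possible for general dissimilarities) are dropped from the
coordinates and from the variance-explained denominator with a warning; each
axis's sign is canonicalized by making its largest-magnitude loading
positive, so different eigensolvers give identical output.  The
`n_axes_for_90pct` field implements the "inspect components until 90% of
variance" rule of thumb.

Counts are log-transformed as log₂(x + offset) before distance computation.
The offset defaults to 1.0 (log₂(x+1)); 0.5 gives the continuity-corrected
variant and is exposed as a parameter everywhere the transform is used.

## Sex-misannotation screen

`check_misannotation` restricts to genes on one chromosome (default Y, with
"M" accepted as an alias of "MT" throughout chromosome handling),
log-transforms, embeds with PCoA, and clusters samples by k-means with k=2
(10 restarts, fixed seed) on the first axis.  Each cluster takes the
majority recorded label among its non-"unknown" members; samples
contradicting their cluster's majority are flagged.  Samples recorded as
"unknown" are clustered but never flagged — there is nothing to contradict.
If all pairwise distances are ~0 the geometry is degenerate: the screen
returns no flags and a warning rather than inventing clusters.

The underlying decision in the original workflow this automates was visual
(inspecting PCoA plots).  The explicit rule — first axis only, 2-means —
works because a binary biological label separates on the leading axis when
it separates at all; an option to cluster on the axes covering 90% of
variance is provided for less clean cases, and the ordination itself is
always returned for human inspection.

## Merge assessment

`assess_merge` asks whether sub-sites of one major site are
transcriptionally distinguishable.  Procedure: restrict to the site's
samples; drop X, Y and mitochondrial genes (sex composition and
mitochondrial load differ between sampling sites for reasons unrelated to
the question); rank genes by unbiased variance of log₂(count+offset) and
keep the top 1000 (the ranking is on the log scale — raw-scale variance is
dominated by the few highest-expressed genes); PCoA; then score the
sub-site labels by mean silhouette in the first two axes.

The silhouette thresholds are 0.25 (below: merge) and 0.5 (above: keep
separate), with an "inspect" verdict between.  These are operating points,
not estimates: silhouette near 0 means the labels explain none of the
geometry, and above 0.5 clusters are well separated by the usual reading of
the statistic.  Both thresholds are parameters.  Iterative re-grouping
(assess, merge the indistinguishable pair, re-assess the remainder) is
supported by re-running the assessment on subsets; the stopping rule is the
analyst's.

## Filtering

CPM(i,j) = counts(i,j)/library_size(j) × 10⁶, with library sizes recomputed
from the matrix as passed in (post any upstream filtering) — the simplest
auditable contract, and it is logged.  The low-expression rule keeps gene i
iff #{j : CPM(i,j) ≥ c} ≥ m with c = 1 by default and

* tissue-aware: m = (smallest merged-group size)/2,
* tissue-agnostic: m = (total samples)/2.

Three boundary conventions are fixed deliberately: the CPM comparison is ≥
(a gene must *reach* one CPM); m is kept as an exact real — 7/2 = 3.5, no
ceil/floor — and compared with ≥, which coincides with ceiling for integer
thresholds; and pass counts are pooled over all samples, with the smallest
group entering only through the threshold.  Pooling (rather than requiring
the passes inside one group) is the literal reading of the rule and makes
the bundled table's arithmetic exact: smallest group 36 ⇒ "at least 18
samples".  A per-group variant would be stricter for scattered expression;
the pooled choice is flagged here because the convention is not universal.

Since m_aware ≤ m_agnostic always, the tissue-aware gene set is a superset
of the agnostic one; the difference is exactly the genes expressed in groups
smaller than half the cohort.  The test suite asserts this as an invariant
and the planted-gene acceptance check exercises it in 100/100 constructed
fixtures.

Chromosome and missing-gene filters are bookkeeping: remove/keep by
chromosome set, and drop genes with zero total count.  `biotype_summary`
tallies gene classes so a filtered set can be characterized (e.g. what
fraction of survivors are protein coding versus pseudogenes).

## Normalization

**Full quantile normalization.** Reference value at rank k = mean over
samples of the k-th order statistic; each sample's value at rank k is
replaced by reference[k].  **Per-group quantile normalization** applies this
independently within each group (singleton groups pass through with a
warning).

**Smooth quantile normalization** interpolates between the two.  At each
rank k, with Q(k,j) the order statistics, q̄_k the global and q̄_{g,k} the
group references:

    SST_k = Σ_j (Q(k,j) − q̄_k)²
    SSB_k = Σ_g n_g (q̄_{g,k} − q̄_k)²
    ŵ_k  = 1 − SSB_k/SST_k          (1 when SST_k = 0)

and sample j in group g gets w_k·q̄_k + (1−w_k)·q̄_{g,k} at rank k.  The raw
weights are smoothed by a centered running median over a window of 5% of the
genes (rounded, forced odd; the window shrinks symmetrically at the edges
via min_periods=1, avoiding zero-padding artifacts) and clamped to [0,1].
Window 1 (or `window_fraction=0`) disables smoothing, which is what the
literal-transcription oracle test uses.  Forcing w≡0 or w≡1 reproduces
per-group and global quantile normalization exactly — checked as acceptance
identities.

Two numerical details shared by all three normalizers:

* **Ties.** Tied values within a sample receive the mean of the target
  values over the tied ranks.  Count data is tie-heavy at zero, so an
  unstated tie rule would make outputs irreproducible across
  implementations; this rule also preserves each sample's total relative to
  the reference.
* **Monotone targets.** The per-rank blend of two ascending references can
  dip slightly where w_k varies; the blended target is sorted before
  assignment, restoring the defining property of a quantile function and
  guaranteeing that normalization never reorders a sample's values.  The
  sort is a no-op whenever the blend is already monotone (always true for
  constant weights).

Zeros are included in all quantile computations — the zero spike is
precisely what the group references must absorb, so trimming it would
defeat the method.  Output is continuous and not re-rounded.
`normalize_tissue_aware` stores the result as a `"normalized"` assay
alongside the untouched raw counts and always recomputes from raw, so
re-running is idempotent.

**RMSE diagnostic.** For sample j, RMSE_j = √(mean_k (log₂(Q(k,j)+offset) −
log₂(ref(k)+offset))²) against the global or the sample's-group reference.
References are computed on raw quantiles: the diagnostic motivates the
choice of normalization, so it must precede it.  On heterogeneous simulated
groups the group-reference RMSE is lower than the global in ≥19/20 seeds
(acceptance check); the margin grows with the tissue-specific fraction.

## Synthetic data generator

`simulate_experiment` draws baseline gene means log-normal(μ=2, σ=1) —
median ≈ 7 counts with a long right tail, a realistic shape for bulk
libraries at desk scale — then plants, per group, a disjoint set of
group-specific genes (10% of genes by default, split across groups) whose
mean is multiplied by 2^shift (default shift 2 log₂) within the group and
set to 0.05 outside it.  Near-zero rather than structurally zero outside
means the CPM boundary is actually exercised and all-zero rows occur only
where planted.  Y-marker genes (default 20) have mean 60 in genetically
male samples and 0.05 otherwise — a log₂ separation far above the ≥4
regime the screen is specified to detect, matching the reality that
Y-linked marker expression is not subtle.  Counts are negative binomial
with variance μ + φμ² (default φ = 0.5, typical bulk over-dispersion);
per-sample library variation multiplies the expected means by a uniform
factor in [0.7, 1.3] before drawing, so counts stay integral.
Misannotation is injected by flipping the *recorded* sex of
round(rate × n) samples while leaving their profiles untouched; the truth
object lists the flipped ids, the planted gene sets, and the full mean
matrix.

Determinism: one master seed spawns a fixed substream per sample plus one
for gene-level parameters (`SeedSequence([seed, stream, j])`), so outputs
are bit-identical across runs and independent of generation order.

`simulate_mergeable_subsites` builds the two-sub-site case for merge
testing: a planted mean shift of `shift_log2` in a fraction of genes
(default 30%), with shift 0 giving identically distributed sub-sites.

What the generator does **not** emulate: batch and center effects,
GC/length biases, donor correlation across tissues, realistic per-tissue
distribution shapes, and partial-expression misannotation (e.g. sex
mosaicism).  Tests passing on this generator therefore demonstrate that the
algorithms recover the structure they are specified to recover under their
own model assumptions — not that real-cohort error rates will match.

## Pipeline and problem sizes

`run_pipeline` fixes the stage order — sex QC, optional removal of flagged
samples, merge-map application, low-expression filtering, normalization —
and records (samples, genes, groups) after every stage, writing the summary
as TSV and JSON next to the outputs.  A flat YAML config with
command-line-flag precedence makes runs serializable; identical config and
seed give byte-identical output tables.

The test and acceptance workloads use simulations of roughly 150–500 genes
and 20–40 samples across up to 50 seeds per check.  These sizes put every
decision boundary (CPM thresholds, silhouette thresholds, cluster majority
votes) in play while keeping the full suite fast; the algorithms themselves
are vectorized and scale to cohort-sized matrices, with PCoA's O(n³)
eigendecomposition in sample count the first practical limit.

## Known limitations

* The bundled 49-sub-site/38-group tissue table records the outcome of one
  large study's merge analysis; applying it to other studies is a modeling
  choice, not a default.
* The sex screen assumes exactly two expression-separable classes on the
  marker chromosome; unusual karyotypes or partial degradation of Y signal
  land between clusters and can be flagged or missed — the report always
  carries the ordination so such cases can be inspected.
* Silhouette on two PCoA axes can miss separation that lives in later axes;
  the ordination object exposes `n_axes_for_90pct` for deeper inspection.
* Pre-filter gene universes differ across annotation releases (the ~55k
  mapped transcripts of the motivating study are reported inconsistently at
  55,019/55,003); the container deliberately takes whatever universe it is
  given and tallies rather than resolves such discrepancies.
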