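"""Annotated expression container shared by every pipeline stage.

The central object is :class:`ExpressionExperiment`: a genes-by-samples
count matrix plus a gene annotation table, a sample annotation table, an
optional map of derived assays (e.g. ``"normalized"``) with the same shape,
and a provenance log recording every mutating operation.

Counts are stored as floating point even though raw input counts are
integers, so derived assays (which are continuous) share a single matrix
contract.  :func:`validate` checks integrality only for experiments flagged
as raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

GENE_COLUMNS = ("gene_id", "chromosome", "biotype")
SAMPLE_COLUMNS = ("sample_id", "donor_id", "sex", "major_site", "sub_site")

#: Chromosome vocabulary: human autosomes, sex chromosomes, mitochondrion
#: ("MT" canonical, "M" accepted), plus "unknown" for unclassifiable genes.
CHROMOSOMES = frozenset(
    [str(i) for i in range(1, 23)] + ["X", "Y", "MT", "M", "unknown"]
)

SEX_LEVELS = frozenset(["male", "female", "unknown"])


def normalize_chromosome(name: str) -> str:
    """Map a chromosome label to the canonical vocabulary ("M" -> "MT")."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name in ("M", "MT", "mt", "m"):
        return "MT"
    return name if name in CHROMOSOMES else name


@dataclass
class ExpressionExperiment:
    """Genes-by-samples count matrix with aligned annotation tables.

    Parameters
    ----------
    counts
        Non-negative genes-by-samples matrix of raw read counts (float
        storage; see module docstring).
    gene_table
        One row per gene, columns at least ``gene_id``, ``chromosome``,
        ``biotype`` (optionally ``symbol``).  Row order matches ``counts``.
    sample_table
        One row per sample, columns at least ``sample_id``, ``donor_id``,
        ``sex``, ``major_site``, ``sub_site`` (optionally ``merged_group``).
        Row order matches ``counts`` columns.
    assays
        Named additional genes-by-samples matrices (same shape as counts).
    provenance_log
        Ordered records of the operations that produced this experiment.
    raw
        Whether ``counts`` are raw integer read counts (checked by
        :func:`validate`).
    """

    counts: np.ndarray
    gene_table: pd.DataFrame
    sample_table: pd.DataFrame
    assays: dict = field(default_factory=dict)
    provenance_log: list = field(default_factory=list)
    raw: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.gene_table = self.gene_table.reset_index(drop=True)
        self.sample_table = self.sample_table.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_table["gene_id"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.sample_table["sample_id"].to_numpy()

    def log(self, operation: str, **params) -> None:
        """Append a provenance record for a mutating pipeline call."""
        self.provenance_log.append(
            {
                "operation": operation,
                "parameters": params,
                "timestamp": datetime.now(timezone.utc).isoformat(),
            }
        )

    def copy(self) -> "ExpressionExperiment":
        return ExpressionExperiment(
            counts=self.counts.copy(),
            gene_table=self.gene_table.copy(),
            sample_table=self.sample_table.copy(),
            assays={k: v.copy() for k, v in self.assays.items()},
            provenance_log=list(self.provenance_log),
            raw=self.raw,
        )


def validate(expr: ExpressionExperiment) -> list[str]:
    """Check every container invariant; return violation descriptions.

    Returns an empty list iff the experiment is well formed.  Violations
    name the offending gene / sample / assay so they can be fixed upstream.
    Reporting only: never raises.
    """
    v: list[str] = []
    counts = expr.counts
    if counts.ndim != 2:
        return [f"counts must be 2-D, got ndim={counts.ndim}"]

    n_genes, n_samples = counts.shape
    if len(expr.gene_table) != n_genes:
        v.append(
            f"gene_table has {len(expr.gene_table)} rows but counts has "
            f"{n_genes} gene rows"
        )
    if len(expr.sample_table) != n_samples:
        v.append(
            f"sample_table has {len(expr.sample_table)} rows but counts has "
            f"{n_samples} sample columns"
        )
    for col in GENE_COLUMNS:
        if col not in expr.gene_table.columns:
            v.append(f"gene_table missing required column '{col}'")
    for col in SAMPLE_COLUMNS:
        if col not in expr.sample_table.columns:
            v.append(f"sample_table missing required column '{col}'")
    if v:
        return v

    gene_ids = expr.gene_table["gene_id"]
    sample_ids = expr.sample_table["sample_id"]
    for dup in gene_ids[gene_ids.duplicated()].unique():
        v.append(f"duplicated gene_id '{dup}'")
    for dup in sample_ids[sample_ids.duplicated()].unique():
        v.append(f"duplicated sample_id '{dup}'")
    if (gene_ids.astype(str).str.len() == 0).any():
        v.append("empty gene_id")
    if (sample_ids.astype(str).str.len() == 0).any():
        v.append("empty sample_id")

    bad = ~np.isfinite(counts)
    for i, j in zip(*np.nonzero(bad)):
        v.append(
            f"non-finite count at (gene {gene_ids.iloc[i]}, "
            f"sample {sample_ids.iloc[j]})"
        )
    neg = np.isfinite(counts) & (counts < 0)
    for i, j in zip(*np.nonzero(neg)):
        v.append(
            f"negative count at (gene {gene_ids.iloc[i]}, "
            f"sample {sample_ids.iloc[j]})"
        )
    if expr.raw:
        frac = np.isfinite(counts) & (counts != np.floor(counts))
        for i, j in zip(*np.nonzero(frac)):
            v.append(
                f"non-integer raw count at (gene {gene_ids.iloc[i]}, "
                f"sample {sample_ids.iloc[j]})"
            )

    bad_sex = ~expr.sample_table["sex"].isin(SEX_LEVELS)
    for sid in sample_ids[bad_sex]:
        v.append(f"sample '{sid}' has sex outside {{male, female, unknown}}")
    if "merged_group" in expr.sample_table.columns:
        mg = expr.sample_table["merged_group"]
        empty = mg.notna() & (mg.astype(str).str.len() == 0)
        for sid in sample_ids[empty]:
            v.append(f"sample '{sid}' has empty merged_group")

    for name, mat in expr.assays.items():
        mat = np.asarray(mat)
        if mat.shape != counts.shape:
            v.append(
                f"assay '{name}' shape {mat.shape} does not match counts "
                f"shape {counts.shape}"
            )
    return v


def subset(
    expr: ExpressionExperiment,
    gene_ids: Optional[Sequence[str]] = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> ExpressionExperiment:
    """Return the experiment restricted to the requested genes/samples.

    The result contains exactly the requested rows/columns *in the
    requested order*; annotation tables and all assays are subset
    consistently and the operation is recorded in the provenance log.

    Raises
    ------
    KeyError
        If a requested id does not exist in the experiment.
    """
    gi = np.arange(expr.n_genes)
    si = np.arange(expr.n_samples)

    if gene_ids is not None:
        gene_ids = list(gene_ids)
        pos = {g: i for i, g in enumerate(expr.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"unknown gene id(s): {missing[:10]}")
        gi = np.array([pos[g] for g in gene_ids], dtype=int)
    if sample_ids is not None:
        sample_ids = list(sample_ids)
        pos = {s: i for i, s in enumerate(expr.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing[:10]}")
        si = np.array([pos[s] for s in sample_ids], dtype=int)

    out = ExpressionExperiment(
        counts=expr.counts[np.ix_(gi, si)],
        gene_table=expr.gene_table.iloc[gi].reset_index(drop=True),
        sample_table=expr.sample_table.iloc[si].reset_index(drop=True),
        assays={k: np.asarray(v)[np.ix_(gi, si)] for k, v in expr.assays.items()},
        provenance_log=list(expr.provenance_log),
        raw=expr.raw,
    )
    out.log(
        "subset",
        n_genes=int(len(gi)),
        n_samples=int(len(si)),
        gene_subset=gene_ids is not None,
        sample_subset=sample_ids is not None,
    )
    return out


def make_experiment(
    counts,
    gene_ids: Iterable[str],
    sample_ids: Iterable[str],
    chromosomes: Optional[Iterable[str]] = None,
    biotypes: Optional[Iterable[str]] = None,
    sex: Optional[Iterable[str]] = None,
    major_site: Optional[Iterable[str]] = None,
    sub_site: Optional[Iterable[str]] = None,
    donor_ids: Optional[Iterable[str]] = None,
    raw: bool = True,
) -> ExpressionExperiment:
    """Convenience constructor filling unspecified annotation with defaults."""
    counts = np.asarray(counts, dtype=float)
    gene_ids = list(gene_ids)
    sample_ids = list(sample_ids)
    n_genes, n_samples = counts.shape
    gene_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": list(chromosomes) if chromosomes is not None
            else ["unknown"] * n_genes,
            "biotype": list(biotypes) if biotypes is not None
            else ["unknown"] * n_genes,
        }
    )
    sample_table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": list(donor_ids) if donor_ids is not None else sample_ids,
            "sex": list(sex) if sex is not None else ["unknown"] * n_samples,
            "major_site": list(major_site) if major_site is not None
            else ["unknown"] * n_samples,
            "sub_site": list(sub_site) if sub_site is not None
            else ["unknown"] * n_samples,
        }
    )
    return ExpressionExperiment(counts, gene_table, sample_table, raw=raw)
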