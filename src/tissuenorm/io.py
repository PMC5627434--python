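"""Reading and writing the on-disk interchange formats.

Two count-matrix dialects are supported, both genes-by-samples:

* ``tsv_dense`` — a tab-separated table with the gene id in the first
  column and a header row of sample ids (canonical dense dialect).
* ``matrix_market`` — MatrixMarket coordinate format with two sidecar
  files of newline-delimited gene ids (rows) and sample ids (columns).

Sample and gene annotation tables are UTF-8 TSV with a mandatory header.
Required sample columns: ``sample_id donor_id sex major_site sub_site``;
required gene columns: ``gene_id chromosome biotype``.  Extra columns pass
through untouched; missing chromosome/biotype values read as "unknown".
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import (
    ExpressionExperiment,
    GENE_COLUMNS,
    SAMPLE_COLUMNS,
    normalize_chromosome,
    validate,
)

PathLike = Union[str, Path]


@dataclass
class CountMatrixDialect:
    """How the count matrix is laid out on disk (orientation fixed)."""

    format: str = "tsv_dense"  # or "matrix_market"
    orientation: str = "genes_by_samples"
    has_header: bool = True
    id_column: str = "gene_id"

    def __post_init__(self) -> None:
        if self.format not in ("tsv_dense", "matrix_market"):
            raise ValueError(f"unknown dialect format '{self.format}'")
        if self.orientation != "genes_by_samples":
            raise ValueError("orientation is fixed to genes_by_samples")


TSV_DENSE = CountMatrixDialect("tsv_dense")
MATRIX_MARKET = CountMatrixDialect("matrix_market")


def _read_table(path: PathLike, required: tuple, kind: str) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # parse failure with context
        raise ValueError(f"failed to parse {kind} table {path}: {exc}") from exc
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{kind} table {path} missing column(s) {missing}")
    return table


def _mismatch(kind: str, left: list, right: list) -> str:
    extra = sorted(set(left) - set(right))[:10]
    absent = sorted(set(right) - set(left))[:10]
    return (
        f"{kind} ids in counts do not match {kind} table: "
        f"only-in-counts={extra}, only-in-table={absent}"
    )


def read_experiment(
    counts_path: PathLike,
    sample_table_path: PathLike,
    gene_table_path: PathLike,
    dialect: CountMatrixDialect = TSV_DENSE,
) -> ExpressionExperiment:
    """Load a validated :class:`ExpressionExperiment` from disk.

    Counts columns are reordered to the sample-table order and rows to
    the gene-table order (a permutation is logged, never an error); id
    *set* mismatches raise with the first 10 offenders listed.
    """
    sample_table = _read_table(sample_table_path, SAMPLE_COLUMNS, "sample")
    gene_table = _read_table(gene_table_path, GENE_COLUMNS, "gene")
    for col in ("chromosome", "biotype"):
        blank = gene_table[col].astype(str).str.len() == 0
        gene_table.loc[blank, col] = "unknown"
    gene_table["chromosome"] = gene_table["chromosome"].map(normalize_chromosome)

    if dialect.format == "tsv_dense":
        frame = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts = frame.to_numpy(dtype=float)
        row_ids = [str(g) for g in frame.index]
        col_ids = [str(s) for s in frame.columns]
    else:
        counts_path = Path(counts_path)
        mat = scipy.io.mmread(counts_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        counts = np.asarray(mat, dtype=float)
        row_ids = _read_ids(counts_path.with_suffix(".rows"))
        col_ids = _read_ids(counts_path.with_suffix(".cols"))
        if len(row_ids) != counts.shape[0] or len(col_ids) != counts.shape[1]:
            raise ValueError(
                f"sidecar id counts ({len(row_ids)} rows, {len(col_ids)} cols)"
                f" do not match matrix shape {counts.shape}"
            )

    if set(col_ids) != set(sample_table["sample_id"]):
        raise ValueError(_mismatch("sample", col_ids, list(sample_table["sample_id"])))
    if set(row_ids) != set(gene_table["gene_id"]):
        raise ValueError(_mismatch("gene", row_ids, list(gene_table["gene_id"])))
    if np.any(counts < 0):
        i, j = np.argwhere(counts < 0)[0]
        raise ValueError(
            f"negative count at gene '{row_ids[i]}', sample '{col_ids[j]}'"
        )

    col_pos = {s: i for i, s in enumerate(col_ids)}
    row_pos = {g: i for i, g in enumerate(row_ids)}
    col_order = [col_pos[s] for s in sample_table["sample_id"]]
    row_order = [row_pos[g] for g in gene_table["gene_id"]]
    permuted = col_order != sorted(col_order) or row_order != sorted(row_order)
    counts = counts[np.ix_(row_order, col_order)]

    expr = ExpressionExperiment(counts, gene_table, sample_table)
    expr.log(
        "read_experiment",
        counts_path=str(counts_path),
        dialect=dialect.format,
        reordered_to_table_order=bool(permuted),
    )
    problems = validate(expr)
    if problems:
        raise ValueError("invalid experiment on load: " + "; ".join(problems[:10]))
    return expr


def _read_ids(path: Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_matrix(
    mat: np.ndarray,
    gene_ids,
    sample_ids,
    path: Path,
    dialect: CountMatrixDialect,
) -> list[Path]:
    if dialect.format == "tsv_dense":
        frame = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
        frame.index.name = dialect.id_column
        # %.12g keeps integer counts integral and floats to 12 sig. digits
        frame.to_csv(path, sep="\t", float_format="%.12g")
        return [path]
    sparse = scipy.sparse.coo_matrix(mat)
    scipy.io.mmwrite(str(path), sparse, precision=12)
    rows = path.with_suffix(".rows")
    cols = path.with_suffix(".cols")
    rows.write_text("\n".join(map(str, gene_ids)) + "\n", encoding="utf-8")
    cols.write_text("\n".join(map(str, sample_ids)) + "\n", encoding="utf-8")
    return [path, rows, cols]


def write_experiment(
    expr: ExpressionExperiment,
    out_dir: PathLike,
    dialect: CountMatrixDialect = TSV_DENSE,
    basename: str = "counts",
) -> list[Path]:
    """Write counts, annotation tables, assays and provenance to ``out_dir``.

    Returns the list of files written: the counts matrix (plus sidecars for
    MatrixMarket), ``genes.tsv``, ``samples.tsv``, ``provenance.log``, and
    one extra matrix per assay suffixed with the assay name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory {out_dir} is not writable")

    ext = ".tsv" if dialect.format == "tsv_dense" else ".mtx"
    written = _write_matrix(
        expr.counts, expr.gene_ids, expr.sample_ids, out_dir / f"{basename}{ext}",
        dialect,
    )
    for name, mat in expr.assays.items():
        written += _write_matrix(
            np.asarray(mat), expr.gene_ids, expr.sample_ids,
            out_dir / f"{basename}.{name}{ext}", dialect,
        )

    genes_path = out_dir / "genes.tsv"
    samples_path = out_dir / "samples.tsv"
    expr.gene_table.to_csv(genes_path, sep="\t", index=False)
    expr.sample_table.to_csv(samples_path, sep="\t", index=False)

    log_path = out_dir / "provenance.log"
    with open(log_path, "w", encoding="utf-8") as fh:
        for record in expr.provenance_log:
            fh.write(
                f"{record['timestamp']}\t{record['operation']}\t"
                f"{record['parameters']}\n"
            )
    return written + [genes_path, samples_path, log_path]
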