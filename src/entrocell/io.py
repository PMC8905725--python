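"""Count-matrix I/O and cell-level quality control.

Supports the 10x-style Matrix Market triplet (matrix.mtx + barcodes.tsv +
features.tsv) and dense (optionally gzipped) TSV/CSV tables, plus the
2-3 column annotation and pseudotime tables the trajectory analysis
consumes.  Entropy is computed on raw counts, so the container enforces
non-negative integer values throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConfigError, DataError, EmptyResultError

log = logging.getLogger(__name__)


class CountMatrix:
    """Genes x cells raw integer counts with unique identifiers.

    Counts are held as a CSR sparse matrix (int64); row/column slicing and
    iteration over nonzeros are both supported.  ``gene_symbols`` carries
    display symbols when the source distinguishes ids from symbols (10x
    features files); it defaults to the ids.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        cell_ids: Sequence[str],
        counts,
        gene_symbols: Sequence[str] | None = None,
    ) -> None:
        gene_ids = list(map(str, gene_ids))
        cell_ids = list(map(str, cell_ids))
        if len(set(gene_ids)) != len(gene_ids):
            raise DataError("duplicate gene identifiers")
        if len(set(cell_ids)) != len(cell_ids):
            raise DataError("duplicate cell identifiers")
        X = sp.csr_matrix(counts)
        if X.shape != (len(gene_ids), len(cell_ids)):
            raise DataError(
                f"counts shape {X.shape} does not match "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells"
            )
        if X.nnz and not np.issubdtype(X.dtype, np.integer):
            if not np.all(X.data == np.floor(X.data)):
                raise DataError("non-integer count entries")
        X = X.astype(np.int64)
        if X.nnz and X.data.min() < 0:
            raise DataError("negative count entries")
        X.eliminate_zeros()
        self.gene_ids = gene_ids
        self.cell_ids = cell_ids
        self.counts = X
        self.gene_symbols = (
            list(map(str, gene_symbols)) if gene_symbols is not None else list(gene_ids)
        )
        if len(self.gene_symbols) != len(gene_ids):
            raise DataError("gene_symbols length mismatch")
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(cell_ids)}

    # -- basic views -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genes, self.n_cells)

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def subset_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        """Column subset in the given order (ids must exist)."""
        try:
            idx = [self._cell_index[c] for c in cell_ids]
        except KeyError as e:
            raise DataError(f"unknown cell id: {e.args[0]!r}") from None
        return CountMatrix(
            self.gene_ids, list(cell_ids), self.counts[:, idx], self.gene_symbols
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        try:
            idx = [self._gene_index[g] for g in gene_ids]
        except KeyError as e:
            raise DataError(f"unknown gene id: {e.args[0]!r}") from None
        return CountMatrix(
            list(gene_ids),
            self.cell_ids,
            self.counts[idx, :],
            [self.gene_symbols[i] for i in idx],
        )

    def drop_genes(self, gene_ids) -> "CountMatrix":
        drop = set(gene_ids)
        keep = [g for g, s in zip(self.gene_ids, self.gene_symbols)
                if g not in drop and s not in drop]
        return self.subset_genes(keep)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and (self.counts != other.counts).nnz == 0
        )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCConfig:
    """Cell-level filters: detected-gene range and mitochondrial fraction.

    A cell is retained when min_genes_per_cell <= (#genes with count > 0)
    <= max_genes_per_cell and mito_counts / total_counts < max_mito_fraction
    (strict).  Mitochondrial genes are identified by gene-symbol prefix.
    """

    min_genes_per_cell: int = 500
    max_genes_per_cell: int = 4000
    max_mito_fraction: float = 0.15
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell > self.max_genes_per_cell:
            raise ConfigError("min_genes_per_cell exceeds max_genes_per_cell")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ConfigError("max_mito_fraction must lie in [0, 1]")


def qc_filter_cells(matrix: CountMatrix, config: QCConfig = QCConfig()) -> CountMatrix:
    """Apply the cell-level QC filters; genes are never removed.

    Cells with zero total counts have their mitochondrial fraction defined
    as 0 (they are removed by the detected-gene minimum whenever it is
    positive).
    """
    if matrix.n_cells == 0:
        raise DataError("empty matrix")
    X = matrix.counts.tocsc()
    detected = np.diff(X.indptr)  # nonzeros per cell
    totals = np.asarray(X.sum(axis=0)).ravel()
    mito_rows = [
        i for i, s in enumerate(matrix.gene_symbols)
        if s.upper().startswith(config.mito_gene_prefix.upper())
    ]
    mito = (
        np.asarray(X[mito_rows, :].sum(axis=0)).ravel()
        if mito_rows
        else np.zeros(matrix.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    keep = (
        (detected >= config.min_genes_per_cell)
        & (detected <= config.max_genes_per_cell)
        & (frac < config.max_mito_fraction)
    )
    n_keep = int(keep.sum())
    log.info("QC: retaining %d / %d cells", n_keep, matrix.n_cells)
    if n_keep == 0:
        raise EmptyResultError("QC removed every cell")
    kept_ids = [c for c, k in zip(matrix.cell_ids, keep) if k]
    return matrix.subset_cells(kept_ids)


# ---------------------------------------------------------------------------
# Matrix Market triplet
# ---------------------------------------------------------------------------

def read_matrix_market_triplet(dir_path: str | Path) -> CountMatrix:
    """Read a 10x-style triplet directory (matrix.mtx, barcodes.tsv, features.tsv).

    Gene ids come from the features file's first column; symbols (second
    column, if present) are kept as metadata.  Duplicate symbols are
    disambiguated by suffixing.
    """
    d = Path(dir_path)
    mtx, barcodes, features = d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv"
    for f in (mtx, barcodes, features):
        if not f.exists():
            raise DataError(f"missing file: {f}")
    X = scipy.io.mmread(mtx)
    X = sp.csr_matrix(X)
    if not np.issubdtype(X.dtype, np.integer):
        if X.nnz and not np.all(X.data == np.floor(X.data)):
            raise DataError(f"non-integer entries in {mtx}")
        X = X.astype(np.int64)
    cells = barcodes.read_text().splitlines()
    feat = [line.split("\t") for line in features.read_text().splitlines()]
    gene_ids = [row[0] for row in feat]
    symbols = [row[1] if len(row) > 1 else row[0] for row in feat]
    if X.shape[0] != len(gene_ids):
        raise DataError(
            f"matrix declares {X.shape[0]} genes but features.tsv has {len(gene_ids)} lines"
        )
    if X.shape[1] != len(cells):
        raise DataError(
            f"matrix declares {X.shape[1]} cells but barcodes.tsv has {len(cells)} lines"
        )
    seen: dict[str, int] = {}
    uniq_symbols = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            log.warning("duplicate gene symbol %r disambiguated", s)
            uniq_symbols.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            uniq_symbols.append(s)
    return CountMatrix(gene_ids, cells, X, uniq_symbols)


def write_matrix_market_triplet(matrix: CountMatrix, dir_path: str | Path) -> None:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(d / "matrix.mtx", matrix.counts.tocoo(), field="integer")
    # mmwrite appends .mtx if absent; normalise the name
    if (d / "matrix.mtx.mtx").exists():
        (d / "matrix.mtx.mtx").rename(d / "matrix.mtx")
    (d / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")
    (d / "features.tsv").write_text(
        "\n".join(
            f"{g}\t{s}\tGene Expression"
            for g, s in zip(matrix.gene_ids, matrix.gene_symbols)
        )
        + "\n"
    )


# ---------------------------------------------------------------------------
# Dense tables
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    name = path.name.removesuffix(".gz")
    return "," if name.endswith(".csv") else "\t"


def read_dense_table(path: str | Path, orientation: str = "genes_in_rows") -> CountMatrix:
    """Read a dense count table with identifiers in the first row and column."""
    if orientation not in ("genes_in_rows", "cells_in_rows"):
        raise ConfigError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    values = df.to_numpy()
    bad = np.argwhere(~(np.isfinite(values) & (values == np.floor(values)) & (values >= 0)))
    if bad.size:
        r, c = bad[0]
        raise DataError(
            f"invalid count {values[r, c]!r} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if orientation == "cells_in_rows":
        df = df.T
    return CountMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=np.int64))


def write_dense_table(
    matrix: CountMatrix, path: str | Path, orientation: str = "genes_in_rows"
) -> None:
    df = pd.DataFrame(matrix.dense(), index=matrix.gene_ids, columns=matrix.cell_ids)
    if orientation == "cells_in_rows":
        df = df.T
    df.to_csv(path, sep=_sep_for(Path(path)))


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Cell annotation table: cell_id, population_label[, sample_id]."""
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_id", "population_label"):
        if col not in df.columns:
            raise DataError(f"annotation table lacks column {col!r}")
    if "sample_id" not in df.columns:
        df["sample_id"] = "sample"
    dup = df.duplicated(subset=["cell_id", "sample_id"])
    if dup.any():
        raise DataError(f"duplicate cell_id within a sample: {df.loc[dup, 'cell_id'].iloc[0]!r}")
    return df


def read_pseudotime(path: str | Path) -> pd.DataFrame:
    """Pseudotime table: cell_id, pseudotime (finite, >= 0)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_id", "pseudotime"):
        if col not in df.columns:
            raise DataError(f"pseudotime table lacks column {col!r}")
    if df["cell_id"].duplicated().any():
        raise DataError("duplicate cell_id in pseudotime table")
    pt = df["pseudotime"].to_numpy(dtype=float)
    if not np.all(np.isfinite(pt)) or np.any(pt < 0):
        raise DataError("pseudotime values must be finite and non-negative")
    return df


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a TSV with '# key=value' reproducibility header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
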