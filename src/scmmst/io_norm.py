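"""Count-matrix I/O, gene filtering, CPM and TMM normalization.

Counts are stored genes x cells.  Normalization factors are the
trimmed-mean-of-M-values (TMM) factors; they enter the mixed model as a
per-cell additive offset ``log(lib_size * tmm_factor / 1e6)`` on the log-link
scale.  Simulated data are depth-homogeneous, so simulation-driven analyses
run with normalization disabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import scipy.stats


class MalformedInputError(ValueError):
    """Raised when an input file violates the count-matrix contract."""


@dataclass
class CountMatrix:
    """Non-negative integer counts, genes in rows, cells in columns."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if self.values.ndim != 2:
            raise MalformedInputError("count matrix must be two-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise MalformedInputError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if np.any(self.values < 0):
            raise MalformedInputError("counts must be non-negative")
        if np.any(self.values != np.floor(self.values)):
            raise MalformedInputError("counts must be integral")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise MalformedInputError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise MalformedInputError("duplicate cell ids")
        self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class CellDesign:
    """Per-cell batch and group labels.

    ``batch_index``/``group_index`` are integer codes into ``batch_levels`` /
    ``group_levels``; ``batch_onehot`` is the n x p dummy matrix B.
    """

    batch: list[str]
    group: list[str]

    def __post_init__(self) -> None:
        self.batch = list(map(str, self.batch))
        self.group = list(map(str, self.group))
        if len(self.batch) != len(self.group):
            raise ValueError("batch and group labels must have equal length")
        self.batch_levels = sorted(set(self.batch))
        self.group_levels = sorted(set(self.group))
        if len(self.batch_levels) < 2:
            raise ValueError("need at least 2 batch levels")
        b2i = {lev: i for i, lev in enumerate(self.batch_levels)}
        g2i = {lev: i for i, lev in enumerate(self.group_levels)}
        self.batch_index = np.array([b2i[b] for b in self.batch], dtype=np.intp)
        self.group_index = np.array([g2i[g] for g in self.group], dtype=np.intp)
        counts = np.bincount(self.batch_index, minlength=len(self.batch_levels))
        if np.any(counts < 2):
            raise ValueError("every batch level needs at least 2 cells")

    @property
    def n_cells(self) -> int:
        return len(self.batch)

    @property
    def n_batches(self) -> int:
        return len(self.batch_levels)

    @property
    def batch_onehot(self) -> np.ndarray:
        B = np.zeros((self.n_cells, self.n_batches))
        B[np.arange(self.n_cells), self.batch_index] = 1.0
        return B

    def group_indicator(self, target_group: str) -> np.ndarray:
        """0/1 vector for the one-against-others contrast of ``target_group``."""
        if str(target_group) not in self.group_levels:
            raise ValueError(
                f"unknown target group {target_group!r}; available: {self.group_levels}"
            )
        return (np.asarray(self.group) == str(target_group)).astype(float)


@dataclass
class NormFactors:
    """Library sizes, TMM factors (geometric mean 1) and log offsets."""

    lib_size: np.ndarray
    tmm_factor: np.ndarray
    offset: np.ndarray


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a genes x cells count matrix from MatrixMarket or dense TSV.

    MatrixMarket input (``.mtx``) expects sibling one-column id files
    ``<stem>.genes.txt`` and ``<stem>.cells.txt``.  TSV input expects a header
    row of cell ids and a first column of gene ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy error text varies
            raise MalformedInputError(f"cannot parse MatrixMarket file {path}: {exc}")
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        gene_file = path.with_suffix(".genes.txt")
        cell_file = path.with_suffix(".cells.txt")
        for f in (gene_file, cell_file):
            if not f.exists():
                raise MalformedInputError(f"missing id file {f}")
        gene_ids = gene_file.read_text().split()
        cell_ids = cell_file.read_text().split()
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise MalformedInputError(
                f"matrix shape {mat.shape} does not match id files "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
        return CountMatrix(np.asarray(mat), gene_ids, cell_ids)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise MalformedInputError(f"non-numeric entries in {path}")
        return CountMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))
    raise ValueError(f"unknown format {format!r}; use 'mtx' or 'tsv'")


def write_counts(cm: CountMatrix, path: str | Path, format: str = "mtx") -> None:
    """Write counts as MatrixMarket coordinate (plus id files) or dense TSV."""
    path = Path(path)
    if format == "mtx":
        sp = scipy.sparse.coo_matrix(cm.values)
        scipy.io.mmwrite(str(path), sp, field="integer")
        # mmwrite may append .mtx; normalize to the requested path
        written = path if path.exists() else path.with_suffix(path.suffix + ".mtx")
        if written != path:
            written.rename(path)
        path.with_suffix(".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        path.with_suffix(".cells.txt").write_text("\n".join(cm.cell_ids) + "\n")
    elif format == "tsv":
        df = pd.DataFrame(cm.values, index=cm.gene_ids, columns=cm.cell_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> CellDesign:
    """Read a cell metadata TSV with columns cell_id, batch, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"cell_id", "batch", "group"} - set(df.columns)
    if missing:
        raise MalformedInputError(f"metadata missing columns: {sorted(missing)}")
    return CellDesign(batch=list(df["batch"]), group=list(df["group"]))


def filter_genes(cm: CountMatrix, min_total: int = 20) -> CountMatrix:
    """Drop genes whose total count across cells is below ``min_total``.

    The default threshold of 20 matches common scRNA-seq preprocessing for
    this test family.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = cm.values.sum(axis=1)
    keep = totals >= min_total
    if not keep.any():
        warnings.warn("all genes removed by the count filter", stacklevel=2)
    return CountMatrix(
        cm.values[keep],
        [g for g, k in zip(cm.gene_ids, keep) if k],
        cm.cell_ids,
    )


def cpm(cm: CountMatrix) -> np.ndarray:
    """Counts-per-million: scale each cell (column) to sum to 1e6."""
    lib = cm.values.sum(axis=0)
    zero = np.where(lib == 0)[0]
    if zero.size:
        raise ValueError(f"cell(s) with zero library size: {[cm.cell_ids[i] for i in zero]}")
    return cm.values * (1e6 / lib)


def _tmm_pair_factor(
    y: np.ndarray, y_ref: np.ndarray, logratio_trim: float, abs_trim: float
) -> float:
    """TMM factor of one cell against the reference cell (log2 scale -> 2**f)."""
    n, n_ref = y.sum(), y_ref.sum()
    pos = (y > 0) & (y_ref > 0)
    if not pos.any():
        warnings.warn("cell shares no expressed gene with reference; factor set to 1", stacklevel=3)
        return 1.0
    yk, yr = y[pos].astype(float), y_ref[pos].astype(float)
    m = np.log2((yk / n) / (yr / n_ref))
    a = 0.5 * (np.log2(yk / n) + np.log2(yr / n_ref))
    w = (n - yk) / (n * yk) + (n_ref - yr) / (n_ref * yr)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    k = m.size
    lo_m = np.floor(k * logratio_trim) + 1
    hi_m = k + 1 - lo_m
    lo_a = np.floor(k * abs_trim) + 1
    hi_a = k + 1 - lo_a
    rank_m = scipy.stats.rankdata(m)
    rank_a = scipy.stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    return float(2.0**f)


def tmm_factors(
    cm: CountMatrix, logratio_trim: float = 0.3, abs_trim: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference cell is the one whose 75th expression quantile (of counts
    scaled by library size) is closest to the mean of those quantiles.  The
    doubly trimmed (30% on log-ratios, 5% on average intensity), precision
    weighted mean of log2 ratios against the reference gives each factor;
    factors are rescaled to geometric mean 1 and the per-cell model offset is
    ``log(lib_size * tmm_factor)``.
    """
    if cm.n_cells < 2:
        raise ValueError("TMM needs at least 2 cells")
    lib = cm.values.sum(axis=0).astype(float)
    if np.any(lib == 0):
        raise ValueError("cells with zero library size cannot be normalized")
    f75 = np.quantile(cm.values / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(cm.values[:, j], cm.values[:, ref], logratio_trim, abs_trim)
            for j in range(cm.n_cells)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(lib_size=lib, tmm_factor=factors, offset=np.log(lib * factors))
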