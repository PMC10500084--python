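"""Reading, validation and normalization of single-cell count matrices.

The internal orientation convention is genes x cells: ``counts[i, j]`` is the
read count of gene ``i`` in cell ``j``.  All readers normalize on-disk layouts
to this convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class DataError(ValueError):
    """Raised for malformed or unusable input data."""


def _as_dense_int(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if scipy.sparse.issparse(values):  # pragma: no cover - callers densify
        arr = values.toarray()
    if arr.size == 0:
        raise DataError(f"{what}: empty matrix")
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{what}: non-finite entries")
    if np.any(arr < 0):
        raise DataError(f"{what}: negative entries are not valid read counts")
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, rtol=0, atol=1e-8):
        raise DataError(f"{what}: non-integer entries are not valid read counts")
    return rounded.astype(np.int64)


@dataclass
class CountMatrix:
    """Raw read counts, genes x cells, with identifiers.

    Invariants (checked on construction): entries are non-negative integers,
    identifiers are unique, at least one gene and two cells.
    """

    counts: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = _as_dense_int(self.counts, "CountMatrix")
        if self.counts.ndim != 2:
            raise DataError("CountMatrix: counts must be 2-dimensional")
        m, n = self.counts.shape
        if not self.gene_ids:
            self.gene_ids = [f"gene_{i}" for i in range(m)]
        if not self.cell_ids:
            self.cell_ids = [f"cell_{j}" for j in range(n)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != m:
            raise DataError("CountMatrix: gene_ids length mismatch")
        if len(self.cell_ids) != n:
            raise DataError("CountMatrix: cell_ids length mismatch")
        if len(set(self.gene_ids)) != m:
            raise DataError("CountMatrix: duplicate gene_ids")
        if len(set(self.cell_ids)) != n:
            raise DataError("CountMatrix: duplicate cell_ids")
        if m < 1 or n < 2:
            raise DataError("CountMatrix: need at least 1 gene and 2 cells")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedMatrix:
    """Size-normalized, log1p-transformed expression, genes x cells."""

    values: np.ndarray
    size_factors: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.size_factors = np.asarray(self.size_factors, dtype=np.float64)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise DataError("NormalizedMatrix: values must be finite and >= 0")
        if np.any(self.size_factors <= 0) or not np.all(np.isfinite(self.size_factors)):
            raise DataError("NormalizedMatrix: size factors must be strictly positive")
        if self.values.shape[1] != self.size_factors.shape[0]:
            raise DataError("NormalizedMatrix: size_factors length mismatch")


def _read_sidecar(path: str) -> Optional[list[str]]:
    if not os.path.exists(path):
        return None
    with open(path) as fh:
        items = [line.split("\t")[0].strip() for line in fh if line.strip()]
    return items or None


def _mtx_sidecars(path: str) -> tuple[Optional[list[str]], Optional[list[str]]]:
    d = os.path.dirname(os.path.abspath(path))
    stem = os.path.splitext(os.path.basename(path))[0]
    genes = _read_sidecar(os.path.join(d, f"{stem}_genes.tsv")) or _read_sidecar(
        os.path.join(d, "genes.tsv")
    ) or _read_sidecar(os.path.join(d, "features.tsv"))
    cells = _read_sidecar(os.path.join(d, f"{stem}_barcodes.tsv")) or _read_sidecar(
        os.path.join(d, "barcodes.tsv")
    )
    return genes, cells


def read_counts(path: str, layout_hint: str = "auto") -> CountMatrix:
    """Read a count matrix from matrix-market, delimited text or an h5ad file.

    Parameters
    ----------
    path:
        Path to ``.mtx`` (with optional ``genes.tsv``/``barcodes.tsv``
        sidecars), ``.csv``/``.tsv`` (first column gene ids, header cell ids),
        or ``.h5ad``.
    layout_hint:
        ``genes_by_cells``, ``cells_by_genes`` or ``auto``.  The returned
        matrix is always genes x cells.
    """
    if layout_hint not in ("auto", "genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown layout_hint {layout_hint!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()

    gene_ids: Sequence[str] = []
    cell_ids: Sequence[str] = []
    if ext == ".mtx":
        mat = scipy.sparse.coo_matrix(scipy.io.mmread(path)).toarray()
        genes, cells = _mtx_sidecars(path)
        layout = layout_hint
        if layout == "auto":
            if genes is not None and cells is not None:
                if mat.shape == (len(genes), len(cells)):
                    layout = "genes_by_cells"
                elif mat.shape == (len(cells), len(genes)):
                    layout = "cells_by_genes"
                else:
                    raise DataError("matrix shape matches neither sidecar layout")
            elif mat.shape[0] == mat.shape[1]:
                raise DataError(
                    "square .mtx without sidecars: orientation is ambiguous, "
                    "pass layout_hint explicitly"
                )
            else:
                layout = "genes_by_cells"
        if layout == "cells_by_genes":
            mat = mat.T
            genes, cells = genes, cells
        if genes is not None and len(genes) == mat.shape[0]:
            gene_ids = genes
        if cells is not None and len(cells) == mat.shape[1]:
            cell_ids = cells
    elif ext in (".csv", ".tsv", ".txt"):
        sep = "," if ext == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = df.to_numpy()
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
        # on-disk convention for delimited files: rows are genes
        layout = "genes_by_cells" if layout_hint == "auto" else layout_hint
        if layout == "cells_by_genes":
            mat = mat.T
            gene_ids, cell_ids = col_ids, row_ids
        else:
            gene_ids, cell_ids = row_ids, col_ids
    elif ext in (".h5ad", ".h5"):
        import anndata

        adata = anndata.read_h5ad(path)
        x = adata.layers["counts"] if "counts" in adata.layers else adata.X
        if scipy.sparse.issparse(x):
            x = x.toarray()
        mat = np.asarray(x)
        # AnnData stores cells x genes
        layout = "cells_by_genes" if layout_hint == "auto" else layout_hint
        if layout == "cells_by_genes":
            mat = mat.T
            gene_ids = [str(v) for v in adata.var_names]
            cell_ids = [str(v) for v in adata.obs_names]
        else:
            gene_ids = [str(v) for v in adata.obs_names]
            cell_ids = [str(v) for v in adata.var_names]
    else:
        raise DataError(f"unsupported file extension {ext!r}")

    return CountMatrix(mat, list(gene_ids), list(cell_ids))


def write_counts(cm: CountMatrix, path: str) -> None:
    """Write counts to ``.mtx`` (with id sidecars), ``.csv``/``.tsv`` or ``.h5ad``."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts), field="integer")
        d = os.path.dirname(os.path.abspath(path))
        stem = os.path.splitext(os.path.basename(path))[0]
        with open(os.path.join(d, f"{stem}_genes.tsv"), "w") as fh:
            fh.write("\n".join(cm.gene_ids) + "\n")
        with open(os.path.join(d, f"{stem}_barcodes.tsv"), "w") as fh:
            fh.write("\n".join(cm.cell_ids) + "\n")
    elif ext in (".csv", ".tsv"):
        sep = "," if ext == ".csv" else "\t"
        pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.cell_ids).to_csv(
            path, sep=sep
        )
    elif ext == ".h5ad":
        import anndata

        adata = anndata.AnnData(X=cm.counts.T.astype(np.float32))
        adata.obs_names = cm.cell_ids
        adata.var_names = cm.gene_ids
        adata.layers["counts"] = cm.counts.T
        adata.write_h5ad(path)
    else:
        raise DataError(f"unsupported file extension {ext!r}")


def preprocess(
    raw: CountMatrix,
    min_cells_per_gene: int = 1,
    target_sum: float = 1e4,
    n_top_genes: Optional[int] = None,
) -> tuple[CountMatrix, NormalizedMatrix]:
    """Filter genes, compute per-cell size factors and log-normalize.

    Genes detected in fewer than ``min_cells_per_gene`` cells are removed.
    The size factor of cell ``j`` is its total count divided by
    ``target_sum``; the normalized value of a count ``c`` is
    ``log(1 + c / size_factor)``.  Returns the filtered raw counts (kept on
    the count scale for the ZINB likelihood) together with the normalized
    matrix.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    counts = raw.counts
    detected = (counts > 0).sum(axis=1)
    keep = detected >= min_cells_per_gene
    if not np.any(keep):
        raise DataError("preprocess: all genes removed by the gene filter")
    counts = counts[keep]
    gene_ids = [g for g, k in zip(raw.gene_ids, keep) if k]

    if n_top_genes is not None and n_top_genes < counts.shape[0]:
        # optional highly-variable-gene selection: variance of log1p values
        lv = np.log1p(counts.astype(np.float64))
        order = np.argsort(lv.var(axis=1))[::-1][:n_top_genes]
        order = np.sort(order)
        counts = counts[order]
        gene_ids = [gene_ids[i] for i in order]

    totals = counts.sum(axis=0).astype(np.float64)
    if np.any(totals == 0):
        bad = [raw.cell_ids[j] for j in np.flatnonzero(totals == 0)]
        raise DataError(f"preprocess: cells with zero total counts: {bad[:5]}")
    size_factors = totals / float(target_sum)
    values = np.log1p(counts / size_factors[None, :])

    filtered = CountMatrix(counts, gene_ids, list(raw.cell_ids))
    return filtered, NormalizedMatrix(values, size_factors)


def read_labels(path: str, cell_ids: Sequence[str]) -> np.ndarray:
    """Read a two-column delimited file (cell_id, label) aligned to ``cell_ids``."""
    sep = "," if path.lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise DataError("label file must have two columns: cell_id, label")
    if list(df.iloc[0]) and df.iloc[0, 0] in ("cell_id", "cell", "barcode"):
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise DataError(f"labels missing for {len(missing)} cells, e.g. {missing[:3]}")
    raw = [mapping[c] for c in cell_ids]
    uniq: dict[str, int] = {}
    out = np.empty(len(raw), dtype=np.int64)
    for j, v in enumerate(raw):
        out[j] = uniq.setdefault(v, len(uniq))
    return out


def write_labels(path: str, cell_ids: Sequence[str], labels: np.ndarray) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), "cluster": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def write_embedding(path: str, cell_ids: Sequence[str], z: np.ndarray) -> None:
    """Write a d x n embedding as a TSV keyed by cell_id."""
    z = np.asarray(z)
    cols = {f"z_{i + 1}": z[i] for i in range(z.shape[0])}
    pd.DataFrame({"cell_id": list(cell_ids), **cols}).to_csv(path, sep="\t", index=False)
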