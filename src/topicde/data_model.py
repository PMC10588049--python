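"""Sparse count-matrix container, I/O, binarization, and feature filtering.

Counts are stored cells x features in CSR format with non-negative integer
values. MatrixMarket files use 1-based indices on disk (per the standard);
everything in memory is 0-based. Name sidecars are plain text, one name per
line, in axis order: ``<path>.rows`` for cells and ``<path>.cols`` for
features. A 10x-style triplet directory (matrix.mtx + barcodes.tsv +
features.tsv/genes.tsv) is accepted as a dialect. Gzip-compressed variants
(.gz) of all of these are accepted.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountsMatrix",
    "SizeFactors",
    "read_counts",
    "write_counts",
    "binarize",
    "filter_features",
    "compute_size_factors",
]


@dataclass
class CountsMatrix:
    """n cells x m features sparse matrix of non-negative integer counts.

    ``modality`` is "rna" for molecule counts or "atac_binarized" for 0/1
    accessibility values.
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str = "rna"

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, m = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(
                f"dimension error: {len(self.cell_ids)} cell names for {n} rows"
            )
        if len(self.feature_ids) != m:
            raise ValueError(
                f"dimension error: {len(self.feature_ids)} feature names for {m} columns"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids contain duplicates")
        if len(set(self.feature_ids)) != m:
            raise ValueError("feature_ids contain duplicates")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("negative values in counts matrix")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integral values in counts matrix")
        if self.modality not in ("rna", "atac_binarized"):
            raise ValueError(f"unknown modality: {self.modality!r}")
        if self.modality == "atac_binarized" and data.size and np.any(data > 1):
            raise ValueError("atac_binarized matrix has values outside {0, 1}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class SizeFactors:
    """Per-cell total counts s_i (all strictly positive)."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float).ravel()
        if np.any(self.s <= 0):
            raise ValueError("size factors must be strictly positive")


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_names(path: str) -> list[str]:
    with _open_text(path) as fh:
        # 10x features.tsv may have multiple tab-separated columns; first wins
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip() != ""]


def _strip_gz(path: str) -> str:
    return path[:-3] if path.endswith(".gz") else path


def _find_sidecar(base: str, suffix: str) -> str:
    for cand in (base + suffix, base + suffix + ".gz"):
        if os.path.exists(cand):
            return cand
    raise FileNotFoundError(f"missing name sidecar {base + suffix}[.gz]")


def _read_mtx(path: str) -> sp.coo_matrix:
    try:
        mat = scipy.io.mmread(path)
    except ValueError as exc:
        raise ValueError(f"parse error in MatrixMarket file {path}: {exc}") from exc
    return sp.coo_matrix(mat)


def _locate_triplet(dirname: str) -> tuple[str, str, str]:
    def pick(names: Sequence[str], what: str) -> str:
        for nm in names:
            p = os.path.join(dirname, nm)
            if os.path.exists(p):
                return p
        raise FileNotFoundError(f"no {what} file in {dirname}")

    mtx = pick(["matrix.mtx", "matrix.mtx.gz"], "matrix.mtx")
    barcodes = pick(["barcodes.tsv", "barcodes.tsv.gz"], "barcodes")
    feats = pick(
        ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"], "features"
    )
    return mtx, barcodes, feats


def read_counts(
    path: str,
    format: str = "mtx",
    transpose: bool = False,
    modality: str = "rna",
) -> CountsMatrix:
    """Read a counts matrix from MatrixMarket (+ name sidecars) or TSV.

    For ``format="mtx"``, ``path`` may be either a .mtx file with
    ``<path-sans-.gz>.rows`` / ``.cols`` sidecars, or a 10x-style triplet
    directory. For ``format="tsv"`` the file has a header row of feature
    names and cell names in the first column. ``transpose=True`` flips the
    on-disk orientation (features x cells) to the internal cells x features.
    """
    if format == "mtx":
        if os.path.isdir(path):
            mtx_path, row_path, col_path = _locate_triplet(path)
            mat = _read_mtx(mtx_path)
            # 10x convention stores features x cells
            mat = mat.T
            cells = _read_names(row_path)
            feats = _read_names(col_path)
        else:
            if not os.path.exists(path):
                raise FileNotFoundError(path)
            mat = _read_mtx(path)
            base = _strip_gz(path)
            cells = _read_names(_find_sidecar(base, ".rows"))
            feats = _read_names(_find_sidecar(base, ".cols"))
        if transpose:
            mat = mat.T
            cells, feats = feats, cells
        mat = sp.csr_matrix(mat)
        if mat.dtype.kind == "f":
            mat = mat.astype(np.int64)
        return CountsMatrix(mat, cells, feats, modality=modality)
    if format == "tsv":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        if transpose:
            df = df.T
        mat = sp.csr_matrix(df.to_numpy(dtype=np.int64))
        return CountsMatrix(
            mat, list(df.index.astype(str)), list(df.columns.astype(str)),
            modality=modality,
        )
    raise ValueError(f"unknown format {format!r}")


def write_counts(x: CountsMatrix, path: str, format: str = "mtx") -> None:
    """Write counts to MatrixMarket + ``.rows``/``.cols`` sidecars, or TSV."""
    if format == "mtx":
        scipy.io.mmwrite(path, x.values.tocoo(), field="integer")
        base = _strip_gz(path)
        with open(base + ".rows", "w") as fh:
            fh.write("\n".join(x.cell_ids) + "\n")
        with open(base + ".cols", "w") as fh:
            fh.write("\n".join(x.feature_ids) + "\n")
    elif format == "tsv":
        import pandas as pd

        pd.DataFrame(
            x.toarray(), index=x.cell_ids, columns=x.feature_ids
        ).to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def binarize(x: CountsMatrix) -> CountsMatrix:
    """Map counts to presence/absence: 1 where count > 0, else 0."""
    v = x.values.copy()
    if v.data.size and np.any(v.data < 0):
        raise ValueError("negative values cannot be binarized")
    v.data = np.ones_like(v.data)
    v.eliminate_zeros()
    return CountsMatrix(
        v.astype(np.int64), list(x.cell_ids), list(x.feature_ids),
        modality="atac_binarized",
    )


def filter_features(x: CountsMatrix, min_cells: int = 0) -> CountsMatrix:
    """Drop invariant features and features nonzero in fewer than min_cells cells.

    "No variation" means every cell shares one identical value, which covers
    all-zero columns and constant-nonzero columns.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    n = x.n_cells
    csc = x.values.tocsc()
    nnz = np.diff(csc.indptr)
    # constant column: either all zero, or nonzero everywhere with a single value
    col_max = csc.max(axis=0).toarray().ravel()
    col_min_nz = np.zeros(x.n_features)
    for j in range(x.n_features):
        d = csc.data[csc.indptr[j]:csc.indptr[j + 1]]
        col_min_nz[j] = d.min() if d.size else 0
    constant = (nnz == 0) | ((nnz == n) & (col_min_nz == col_max))
    keep = (~constant) & (nnz >= min_cells)
    n_const = int(constant.sum())
    if n_const:
        logger.info("filter_features: dropping %d invariant features", n_const)
    if not keep.any():
        raise ValueError("filter_features: no features remain after filtering")
    idx = np.flatnonzero(keep)
    return CountsMatrix(
        csc[:, idx].tocsr(),
        list(x.cell_ids),
        [x.feature_ids[j] for j in idx],
        modality=x.modality,
    )


def compute_size_factors(x: CountsMatrix) -> SizeFactors:
    """Row totals s_i = x_i1 + ... + x_im; errors on all-zero cells."""
    s = np.asarray(x.values.sum(axis=1)).ravel().astype(float)
    if np.any(s == 0):
        bad = [x.cell_ids[i] for i in np.flatnonzero(s == 0)]
        raise ValueError(f"cells with zero total counts: {bad}")
    return SizeFactors(s)
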