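"""Build sample x cell-type x gene pseudobulk tensors from single-cell counts.

Cells are grouped by (sample, cell type) and their gene counts summed, which
respects the correlation structure of cells from the same individual and
yields the 3-way tensor the factorization consumes.  The module also applies
the standard pre-tensor filters — dropping genes without a usable symbol or
with fewer than 50 total counts, and dropping samples/cell types holding less
than 2% of cells — and the per-fiber CPM normalization (every sample-cell
type gene fiber rescaled to 1e6 total counts).

Readers accept the 10x-style Matrix Market triple (counts.mtx + genes/
barcodes tables) or a dense delimited cells x genes table, with cell metadata
as a delimited table keyed by barcode.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .tensors import CountTensor

__all__ = [
    "CellCountMatrix",
    "filter_genes",
    "filter_rare_groups",
    "build_tensor",
    "cpm_normalize",
    "read_10x_mtx",
    "read_dense_counts",
    "attach_cell_meta",
]

CPM_TOTAL = 1e6


@dataclass
class CellCountMatrix:
    """Cells x genes non-negative integer counts with per-cell annotations.

    ``cell_meta`` must carry ``sample`` and ``cell_type`` columns (index
    aligned with count rows); ``gene_ids`` are unique gene symbols/IDs.
    """

    counts: sparse.spmatrix | np.ndarray
    cell_meta: pd.DataFrame
    gene_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sparse.issparse(self.counts):
            self.counts = self.counts.tocsr()
        else:
            self.counts = np.asarray(self.counts)
        n_cells, n_genes = self.counts.shape
        if self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(self.cell_meta) != n_cells:
            raise ValueError(
                f"{len(self.cell_meta)} metadata rows for {n_cells} cells"
            )
        for col in ("sample", "cell_type"):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta lacks required column {col!r}")
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_genes} genes")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_totals(self) -> np.ndarray:
        t = self.counts.sum(axis=0)
        return np.asarray(t).ravel()

    def subset(self, cells=None, genes=None) -> "CellCountMatrix":
        """New matrix restricted to the given integer cell/gene indices."""
        counts, meta, gids = self.counts, self.cell_meta, self.gene_ids
        if cells is not None:
            cells = np.asarray(cells)
            counts = counts[cells]
            meta = meta.iloc[cells]
        if genes is not None:
            genes = np.asarray(genes)
            counts = counts[:, genes]
            gids = list(np.asarray(self.gene_ids)[genes])
        return CellCountMatrix(
            counts, meta.reset_index(drop=True), gids, copy.deepcopy(self.provenance)
        )


def filter_genes(
    m: CellCountMatrix,
    min_total: int = 50,
    require_symbol: bool = False,
    symbols: set[str] | None = None,
) -> CellCountMatrix:
    """Drop genes with total count below ``min_total`` (strictly less than —
    the boundary is kept) and, when ``require_symbol`` is set, genes whose
    identifier is blank or absent from the supplied symbol table."""
    totals = m.gene_totals()
    keep = totals >= min_total
    if require_symbol:
        has_symbol = np.array(
            [bool(g) and not str(g).strip() == "" for g in m.gene_ids]
        )
        if symbols is not None:
            has_symbol &= np.array([g in symbols for g in m.gene_ids])
        keep &= has_symbol
    if not keep.any():
        raise ValueError("gene filtering removed every gene")
    out = m.subset(genes=np.flatnonzero(keep))
    out.provenance.setdefault("filters", []).append(
        {"filter": "genes", "min_total": min_total, "require_symbol": require_symbol,
         "before": m.n_genes, "after": out.n_genes}
    )
    return out


def filter_rare_groups(m: CellCountMatrix, min_frac: float = 0.02) -> CellCountMatrix:
    """Iteratively drop samples and cell types holding < ``min_frac`` of cells.

    Shares are recomputed after each pass until stable, so removing a sample
    can cascade into removing a cell type that falls under the threshold.
    Groups exactly at the threshold are kept.
    """
    if not (0 <= min_frac < 1):
        raise ValueError("min_frac must lie in [0, 1)")
    meta = m.cell_meta
    keep = np.ones(m.n_cells, dtype=bool)
    changed = True
    while changed:
        changed = False
        n = keep.sum()
        if n == 0:
            raise ValueError("rare-group filtering removed every cell")
        for col in ("sample", "cell_type"):
            shares = meta.loc[keep, col].value_counts() / n
            bad = set(shares[shares < min_frac].index)
            if bad:
                keep &= ~meta[col].isin(bad).to_numpy()
                changed = True
                break  # recompute shares before touching the other column
    if keep.sum() == 0:
        raise ValueError("rare-group filtering removed every cell")
    out = m.subset(cells=np.flatnonzero(keep))
    out.provenance.setdefault("filters", []).append(
        {"filter": "rare_groups", "min_frac": min_frac,
         "before": m.n_cells, "after": out.n_cells}
    )
    return out


def build_tensor(m: CellCountMatrix) -> CountTensor:
    """Sum counts over cells per (sample, cell type): a samples x cell types
    x genes tensor.  Missing combinations give all-zero fibers (warned)."""
    meta = m.cell_meta
    unlabeled = meta.index[meta["sample"].isna() | meta["cell_type"].isna()]
    if len(unlabeled):
        raise ValueError(f"cells without labels: {list(unlabeled[:10])}")
    samples = sorted(map(str, meta["sample"].unique()))
    ctypes = sorted(map(str, meta["cell_type"].unique()))
    s_idx = {s: i for i, s in enumerate(samples)}
    c_idx = {c: i for i, c in enumerate(ctypes)}
    data = np.zeros((len(samples), len(ctypes), m.n_genes))
    counts = m.counts
    rows_s = meta["sample"].astype(str).map(s_idx).to_numpy()
    rows_c = meta["cell_type"].astype(str).map(c_idx).to_numpy()
    for si in range(len(samples)):
        for ci in range(len(ctypes)):
            mask = (rows_s == si) & (rows_c == ci)
            if mask.any():
                block = counts[np.flatnonzero(mask)].sum(axis=0)
                data[si, ci] = np.asarray(block).ravel()
    empty = [
        (samples[si], ctypes[ci])
        for si in range(len(samples))
        for ci in range(len(ctypes))
        if data[si, ci].sum() == 0
    ]
    if empty:
        warnings.warn(f"empty sample/cell-type combinations: {empty}", stacklevel=2)
    return CountTensor(
        data,
        mode_names=["sample", "cell_type", "gene"],
        axis_labels=[samples, ctypes, list(m.gene_ids)],
    )


def cpm_normalize(t: CountTensor, total: float = CPM_TOTAL) -> CountTensor:
    """Rescale each (sample, cell type) gene fiber to sum to ``total`` (1e6).

    All-zero fibers are left at zero and reported with a warning.  Idempotent.
    """
    if t.order != 3:
        raise ValueError("cpm_normalize expects a 3-way tensor")
    sums = t.data.sum(axis=2)
    zero = sums == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero sample/cell-type fibers left unscaled",
            stacklevel=2,
        )
    scale = np.where(zero, 1.0, total / np.where(zero, 1.0, sums))
    return CountTensor(
        t.data * scale[:, :, None], mode_names=t.mode_names, axis_labels=t.axis_labels
    )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_10x_mtx(
    directory: str | Path,
    matrix: str = "counts.mtx",
    genes: str = "genes.tsv",
    barcodes: str = "barcodes.tsv",
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Matrix Market counts (cells x genes after transpose-if-needed) plus
    gene and barcode identifier tables."""
    directory = Path(directory)
    mat = spio.mmread(directory / matrix).tocsr()
    gene_ids = pd.read_csv(directory / genes, sep="\t", header=None)[0].tolist()
    cell_ids = pd.read_csv(directory / barcodes, sep="\t", header=None)[0].tolist()
    if mat.shape == (len(gene_ids), len(cell_ids)) and len(gene_ids) != len(cell_ids):
        mat = mat.T.tocsr()  # stored genes x cells, 10x-style
    if mat.shape != (len(cell_ids), len(gene_ids)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(cell_ids)} barcodes "
            f"x {len(gene_ids)} genes"
        )
    return mat, gene_ids, cell_ids


def read_dense_counts(path: str | Path, sep: str = "\t"):
    """Dense delimited cells x genes table with barcode index and gene header."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(), list(df.columns), list(df.index)


def attach_cell_meta(
    counts,
    gene_ids: list[str],
    cell_ids: list[str],
    meta_path: str | Path,
    sep: str = "\t",
    sample_col: str = "sample",
    cell_type_col: str = "cell_type",
) -> CellCountMatrix:
    """Join a barcode-keyed metadata table onto the count matrix."""
    meta = pd.read_csv(meta_path, sep=sep, index_col=0)
    missing = [b for b in cell_ids if b not in meta.index]
    if missing:
        raise ValueError(f"barcodes missing from metadata: {missing[:10]}")
    meta = meta.loc[cell_ids].rename(
        columns={sample_col: "sample", cell_type_col: "cell_type"}
    )
    if "sample" not in meta.columns and "donor" in meta.columns:
        meta = meta.rename(columns={"donor": "sample"})  # simulator fixtures
    return CellCountMatrix(counts, meta.reset_index(drop=True), gene_ids)


def write_provenance(m: CellCountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(m.provenance, fh, indent=1)
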