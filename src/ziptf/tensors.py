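"""Dense count tensors, CP factor sets, and the fit/similarity metrics built on them.

A :class:`CountTensor` is an N-way array of non-negative values (raw or
CPM-normalized counts) with named modes and optional per-mode axis labels
(sample IDs, cell-type names, gene symbols).  A :class:`CPFactors` holds the
non-negative per-mode factor matrices of a rank-R CP (Candecomp/Parafac)
decomposition; ``reconstruct`` turns it back into the dense low-rank tensor
``sum_r a_r^(1) o a_r^(2) o ... o a_r^(N)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CountTensor",
    "CPFactors",
    "frobenius_norm",
    "reconstruct",
    "explained_variance",
    "cosine_score",
    "khatri_rao",
    "save_tensor",
    "load_tensor",
    "save_factors",
    "load_factors",
]


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, CountTensor) else np.asarray(x, dtype=float)


@dataclass
class CountTensor:
    """N-way dense array of non-negative, finite values with labeled modes."""

    data: np.ndarray
    mode_names: list[str] | None = None
    axis_labels: list[list[str]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim < 2:
            raise ValueError("CountTensor requires an array of order >= 2")
        if self.data.size == 0:
            raise ValueError("CountTensor must be non-empty")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CountTensor entries must be finite")
        if np.any(self.data < 0):
            raise ValueError("CountTensor entries must be non-negative")
        if self.mode_names is None:
            self.mode_names = [f"mode_{i}" for i in range(self.data.ndim)]
        if len(self.mode_names) != self.data.ndim:
            raise ValueError(
                f"got {len(self.mode_names)} mode names for an order-"
                f"{self.data.ndim} tensor"
            )
        if self.axis_labels is not None:
            if len(self.axis_labels) != self.data.ndim:
                raise ValueError("axis_labels must provide one list per mode")
            for k, labels in enumerate(self.axis_labels):
                if labels is not None and len(labels) != self.data.shape[k]:
                    raise ValueError(
                        f"mode {k} has {self.data.shape[k]} entries but "
                        f"{len(labels)} labels"
                    )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def order(self) -> int:
        return self.data.ndim


@dataclass
class CPFactors:
    """Non-negative per-mode factor matrices ``A^(k)`` sharing column count R."""

    factors: list[np.ndarray]
    rank: int = field(default=0)

    def __post_init__(self) -> None:
        self.factors = [np.asarray(f, dtype=float) for f in self.factors]
        if len(self.factors) < 2:
            raise ValueError("CPFactors requires at least 2 modes")
        ranks = {f.shape[1] for f in self.factors}
        if len(ranks) != 1:
            raise ValueError(f"factor matrices disagree on rank: {sorted(ranks)}")
        r = ranks.pop()
        if self.rank == 0:
            self.rank = r
        elif self.rank != r:
            raise ValueError(f"declared rank {self.rank} != column count {r}")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        for k, f in enumerate(self.factors):
            if f.ndim != 2:
                raise ValueError(f"factor {k} is not a matrix")
            if np.any(f < 0):
                raise ValueError(f"factor {k} has negative entries")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(f.shape[0] for f in self.factors)

    @property
    def order(self) -> int:
        return len(self.factors)


def frobenius_norm(x: CountTensor | np.ndarray) -> float:
    """Frobenius norm ``sqrt(sum of squared entries)`` of a tensor."""
    a = _as_array(x)
    if a.size == 0:
        raise ValueError("Frobenius norm of an empty tensor is undefined")
    return float(np.sqrt(np.sum(a * a)))


def khatri_rao(matrices: list[np.ndarray]) -> np.ndarray:
    """Column-wise Khatri-Rao product of matrices sharing a column count R.

    Returns a ``(prod I_k) x R`` matrix whose r-th column is the Kronecker
    product of the r-th columns of the inputs (row-major index order).
    """
    out = matrices[0]
    for m in matrices[1:]:
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, m.shape[1])
    return out


def reconstruct(
    f: CPFactors,
    mode_names: list[str] | None = None,
    axis_labels: list[list[str]] | None = None,
) -> CountTensor:
    """Dense tensor ``X~[i1..iN] = sum_r prod_k A^(k)[i_k, r]`` from CP factors."""
    shape = f.shape
    first = f.factors[0]
    kr = khatri_rao(f.factors[1:])  # (prod of other dims) x R
    data = (first @ kr.T).reshape(shape)
    # tiny negative values can appear from float cancellation; factors are >= 0
    np.clip(data, 0.0, None, out=data)
    return CountTensor(data, mode_names=mode_names, axis_labels=axis_labels)


def explained_variance(
    x: CountTensor | np.ndarray,
    xhat: CountTensor | np.ndarray,
    squared: bool = False,
) -> float:
    """Explained variance of an approximation: ``1 - ||x - xhat||_F / ||x||_F``.

    The default is the unsquared ratio of norms.  ``squared=True`` uses the
    conventional variance-style ratio of squared norms instead; both are <= 1
    and can be negative for poor fits.
    """
    a, b = _as_array(x), _as_array(xhat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    nx = frobenius_norm(a)
    if nx == 0:
        raise ValueError("explained variance undefined for an all-zero tensor")
    ratio = frobenius_norm(a - b) / nx
    return float(1.0 - ratio**2) if squared else float(1.0 - ratio)


def _column_cosines(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """R1 x R2 matrix of cosines between columns; zero-norm columns give 0."""
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    denom = np.outer(na, nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, (a.T @ b) / np.where(denom > 0, denom, 1.0), 0.0)
    return c


def cosine_score(f1: CPFactors, f2: CPFactors) -> float:
    """Similarity of two factorizations of a common tensor.

    ``(1/R) sum_i max_j prod_k cos(a_i^(k), d_j^(k))`` — for each component i
    of the first factorization the best-matching component j of the second is
    taken independently (j may be reused across i).  Non-negative factors give
    a score in [0, 1]; identical factorizations score 1.
    """
    if f1.rank != f2.rank:
        raise ValueError(f"rank mismatch: {f1.rank} vs {f2.rank}")
    if f1.shape != f2.shape:
        raise ValueError(f"mode shape mismatch: {f1.shape} vs {f2.shape}")
    prod = np.ones((f1.rank, f2.rank))
    for a, d in zip(f1.factors, f2.factors):
        prod *= _column_cosines(a, d)
    return float(np.mean(np.max(prod, axis=1)))


# ---------------------------------------------------------------------------
# serialization: delimited slices + JSON metadata, and a compact .npz container
# ---------------------------------------------------------------------------


def save_tensor(x: CountTensor, path: str | Path, fmt: str = "tsv") -> None:
    """Write a tensor to ``path``.

    ``fmt='tsv'`` writes a directory with one delimited matrix per leading-mode
    slice (``slice_000.tsv``, ...) plus ``meta.json`` with mode names and axis
    labels.  ``fmt='npz'`` writes a single compact binary container.
    """
    path = Path(path)
    if fmt == "npz":
        meta = json.dumps(
            {"mode_names": x.mode_names, "axis_labels": x.axis_labels}
        )
        np.savez_compressed(path, data=x.data, meta=np.array(meta))
        return
    if fmt != "tsv":
        raise ValueError(f"unknown tensor format {fmt!r}")
    path.mkdir(parents=True, exist_ok=True)
    flat = x.data.reshape(x.shape[0], -1) if x.order == 2 else x.data
    for i in range(x.shape[0]):
        sl = x.data[i]
        if sl.ndim == 1:
            sl = sl[None, :]
        elif sl.ndim > 2:
            sl = sl.reshape(sl.shape[0], -1)
        np.savetxt(path / f"slice_{i:03d}.tsv", sl, delimiter="\t")
    del flat
    with open(path / "meta.json", "w") as fh:
        json.dump(
            {
                "shape": list(x.shape),
                "mode_names": x.mode_names,
                "axis_labels": x.axis_labels,
            },
            fh,
            indent=1,
        )


def load_tensor(path: str | Path) -> CountTensor:
    path = Path(path)
    if path.suffix == ".npz" or path.is_file():
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return CountTensor(z["data"], meta["mode_names"], meta["axis_labels"])
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    shape = meta["shape"]
    slices = [
        np.loadtxt(path / f"slice_{i:03d}.tsv", delimiter="\t", ndmin=2)
        for i in range(shape[0])
    ]
    data = np.stack(slices).reshape(shape)
    return CountTensor(data, meta["mode_names"], meta.get("axis_labels"))


def save_factors(f: CPFactors, path: str | Path, mode_names=None, axis_labels=None):
    """One delimited matrix per mode (columns = components) + JSON metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for k, mat in enumerate(f.factors):
        np.savetxt(path / f"mode_{k}.tsv", mat, delimiter="\t")
    with open(path / "meta.json", "w") as fh:
        json.dump(
            {
                "rank": f.rank,
                "order": f.order,
                "shape": list(f.shape),
                "mode_names": mode_names,
                "axis_labels": axis_labels,
            },
            fh,
            indent=1,
        )


def load_factors(path: str | Path) -> CPFactors:
    path = Path(path)
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    factors = [
        np.loadtxt(path / f"mode_{k}.tsv", delimiter="\t", ndmin=2)
        for k in range(meta["order"])
    ]
    return CPFactors(factors, rank=meta["rank"])
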