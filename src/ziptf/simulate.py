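"""Synthetic data generators: ZIP-noise low-rank tensors and Splatter-style
multi-donor scRNA-seq counts with embedded gene expression programs.

Two generators make the whole pipeline testable without downloads:

``simulate_zip_tensor``
    A known-rank mean tensor ``T = [[A, B, C]]`` with factor entries drawn
    Gamma(shape 3, rate 0.3), observed through zero-inflated Poisson noise:
    each entry is Poisson(T_I) and then zeroed with excess-zero probability
    phi.  The ground-truth factors and mean tensor are kept for scoring.

``simulate_scrnaseq``
    A Gamma-Poisson hierarchical single-cell counts simulator in the Splatter
    family: lognormal library sizes (ln-mean 7.64, ln-sd 0.78), gene means
    from a Gamma with mean 7.68 and shape 0.34 with rare expression outliers
    (probability 0.00286, resampled lognormal ln-mean 6.15 / ln-sd 0.49),
    logistic-in-log-mean dropout applied as Bernoulli masking, and 5%
    doublets formed by merging two cells and downsampling to the larger
    total.  Cell-type *identity* programs and donor-specific *activity*
    programs are embedded as expression profiles (baseline gene means times
    multiplicative DE factors on disjoint, seeded 10% gene subsets); every
    cell's Poisson rate is its library size times a usage-weighted mixture of
    program profiles, and the profiles are exported as the ground-truth GEP
    matrix for recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .tensors import CountTensor, CPFactors, reconstruct

__all__ = [
    "ZipTensorSim",
    "SyntheticSC",
    "simulate_zip_tensor",
    "simulate_scrnaseq",
    "export_fixture",
    "load_fixture",
    "runtime_benchmark_tensor",
]


@dataclass
class ZipTensorSim:
    """A simulated ZIP count tensor with its generating factors."""

    tensor: CountTensor
    true_factors: CPFactors
    phi: float
    seed: int
    mean_tensor: CountTensor = None

    @property
    def zero_fraction(self) -> float:
        return float((self.tensor.data == 0).mean())


@dataclass
class SyntheticSC:
    """Simulated cells x genes counts with donor/cell-type truth."""

    counts: np.ndarray
    cell_meta: pd.DataFrame  # donor, cell_type, is_doublet
    gep_matrix: pd.DataFrame  # genes x programs (normalized profiles)
    usage: np.ndarray  # cells x programs mixture weights
    params: dict = field(default_factory=dict)
    library_sizes: np.ndarray | None = None  # drawn library sizes (pre-doublet cells)
    pre_dropout_counts: np.ndarray | None = None  # counts before dropout masking

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


def simulate_zip_tensor(
    shape: tuple[int, ...],
    rank: int,
    alpha: float = 3.0,
    rate: float = 0.3,
    phi: float = 0.0,
    seed: int = 0,
) -> ZipTensorSim:
    """Low-rank mean tensor with Gamma(alpha, rate) factors observed through
    zero-inflated Poisson noise with excess-zero probability ``phi``."""
    if not (0.0 <= phi <= 1.0):
        raise ValueError("phi must lie in [0, 1]")
    if rank < 1 or len(shape) < 2 or any(d < 1 for d in shape):
        raise ValueError(f"invalid shape {shape} / rank {rank}")
    rng = np.random.default_rng(seed)
    factors = CPFactors(
        [rng.gamma(alpha, 1.0 / rate, size=(d, rank)) for d in shape]
    )
    mean = reconstruct(factors)
    counts = rng.poisson(mean.data).astype(float)
    if phi > 0:
        counts *= rng.random(shape) >= phi
    return ZipTensorSim(CountTensor(counts), factors, phi, seed, mean)


def runtime_benchmark_tensor(shape=(10, 20, 300), seed: int = 0) -> ZipTensorSim:
    """The flatter benchmark preset: Gamma(1, 0.3) factors, rank 10, phi 0.5."""
    return simulate_zip_tensor(shape, rank=10, alpha=1.0, rate=0.3, phi=0.5, seed=seed)


def _designated_donors(n_activity: int, n_donors: int, per_program: int = 3):
    """Distinct donor triples, one per activity program."""
    sets = []
    for p in range(n_activity):
        sets.append(sorted({(2 * p + j) % n_donors for j in range(per_program)}))
    return sets


def simulate_scrnaseq(
    n_cells: int = 3000,
    n_genes: int = 1000,
    n_donors: int = 6,
    n_identity: int = 5,
    n_activity: int = 3,
    mean_de_log2fc: float = 0.75,
    identity_de_log2fc: float = 1.0,
    de_frac: float = 0.10,
    de_log2fc_sd: float = 0.2,
    de_down_prob: float = 0.5,
    dropout: bool = True,
    dropout_midpoint: float = 0.0,
    dropout_shape: float = -1.0,
    doublet_rate: float = 0.05,
    library_ln_mean: float = 7.64,
    library_ln_sd: float = 0.78,
    gene_mean: float = 7.68,
    gene_shape: float = 0.34,
    outlier_prob: float = 0.00286,
    outlier_ln_mean: float = 6.15,
    outlier_ln_sd: float = 0.49,
    activity_usage: tuple[float, float] = (0.15, 0.45),
    seed: int = 0,
) -> SyntheticSC:
    """Simulate multi-donor scRNA-seq counts with identity + activity GEPs.

    ``mean_de_log2fc`` controls the intensity of the donor-specific activity
    programs (the benchmarked signal level); identity programs use the fixed
    ``identity_de_log2fc`` so cell types remain separable across settings.
    Each program boosts a disjoint ``de_frac`` subset of genes by lognormal
    multiplicative factors centered at the requested mean log2 fold change.
    Activity programs attach to designated triples of donors; affected cells
    mix the activity profile into their identity profile with a usage drawn
    uniformly from ``activity_usage``.
    """
    n_programs = n_identity + n_activity
    if round(de_frac * n_genes) * n_programs > n_genes:
        raise ValueError("program gene sets exceed the number of genes")
    rng = np.random.default_rng(seed)

    # baseline gene means with expression outliers
    mu = rng.gamma(gene_shape, gene_mean / gene_shape, size=n_genes)
    outliers = rng.random(n_genes) < outlier_prob
    mu[outliers] = rng.lognormal(outlier_ln_mean, outlier_ln_sd, size=int(outliers.sum()))

    # disjoint DE gene subsets and program expression profiles
    set_size = int(round(de_frac * n_genes))
    perm = rng.permutation(n_genes)
    profiles = np.empty((n_genes, n_programs))
    program_genes = []
    for p in range(n_programs):
        genes_p = perm[p * set_size : (p + 1) * set_size]
        program_genes.append(np.sort(genes_p))
        l2fc = mean_de_log2fc if p >= n_identity else identity_de_log2fc
        fc = np.ones(n_genes)
        lfc = rng.normal(l2fc * np.log(2.0), de_log2fc_sd, size=set_size)
        down = rng.random(set_size) < de_down_prob  # Splatter-style signed DE
        fc[genes_p] = np.exp(np.where(down, -lfc, lfc))
        prof = mu * fc
        profiles[:, p] = prof / prof.sum()

    # cells: balanced donors, uniform identity, activity usage on designated donors
    n_doublets = int(round(doublet_rate * n_cells))
    n_singletons = n_cells - n_doublets
    n_parents = n_singletons + 2 * n_doublets
    donor = rng.integers(0, n_donors, size=n_parents)
    ident = rng.integers(0, n_identity, size=n_parents)
    usage = np.zeros((n_parents, n_programs))
    donor_sets = _designated_donors(n_activity, n_donors)
    lo, hi = activity_usage
    for p, dset in enumerate(donor_sets):
        affected = np.isin(donor, dset)
        usage[affected, n_identity + p] = rng.uniform(lo, hi, size=int(affected.sum()))
    total_act = usage[:, n_identity:].sum(axis=1)
    over = total_act > 0.7  # cap so identity stays the dominant program
    usage[over, n_identity:] *= (0.7 / total_act[over])[:, None]
    usage[np.arange(n_parents), ident] = 1.0 - usage[:, n_identity:].sum(axis=1)

    lib = rng.lognormal(library_ln_mean, library_ln_sd, size=n_parents)
    rates = lib[:, None] * (usage @ profiles.T)
    counts = rng.poisson(rates).astype(np.int64)
    pre_dropout = counts.copy()

    # dropout: per-gene zero probability, logistic in log mean expression
    dropout_p = np.zeros(n_genes)
    if dropout:
        gene_mean_expr = np.clip(rates.mean(axis=0), 1e-12, None)
        dropout_p = 1.0 / (
            1.0 + np.exp(-dropout_shape * (np.log(gene_mean_expr) - dropout_midpoint))
        )
        keep = rng.random(counts.shape) >= dropout_p[None, :]
        counts *= keep

    # doublets: merge two parents, downsample to the larger parent's total
    meta = pd.DataFrame(
        {
            "donor": [f"donor_{d}" for d in donor],
            "cell_type": [f"type_{t}" for t in ident],
            "is_doublet": False,
        }
    )
    if n_doublets:
        pa = np.arange(n_singletons, n_singletons + n_doublets)
        pb = np.arange(n_singletons + n_doublets, n_parents)
        merged_rows, merged_meta = [], []
        for a, b in zip(pa, pb):
            combined = counts[a] + counts[b]
            target = int(max(counts[a].sum(), counts[b].sum()))
            total = int(combined.sum())
            if total > target > 0:
                merged = rng.multinomial(target, combined / total)
            else:
                merged = combined
            merged_rows.append(merged)
            major = a if counts[a].sum() >= counts[b].sum() else b
            merged_meta.append(
                {
                    "donor": f"donor_{donor[major]}",
                    "cell_type": f"type_{ident[major]}",
                    "is_doublet": True,
                }
            )
        counts = np.vstack([counts[:n_singletons], np.array(merged_rows)])
        u_doub = 0.5 * (usage[pa] + usage[pb])
        usage = np.vstack([usage[:n_singletons], u_doub])
        meta = pd.concat(
            [meta.iloc[:n_singletons], pd.DataFrame(merged_meta)], ignore_index=True
        )

    gene_ids = [f"gene_{g:04d}" for g in range(n_genes)]
    prog_ids = [f"identity_{p}" for p in range(n_identity)] + [
        f"activity_{p}" for p in range(n_activity)
    ]
    params = {
        "n_cells": n_cells, "n_genes": n_genes, "n_donors": n_donors,
        "n_identity": n_identity, "n_activity": n_activity,
        "mean_de_log2fc": mean_de_log2fc, "identity_de_log2fc": identity_de_log2fc,
        "de_frac": de_frac, "de_log2fc_sd": de_log2fc_sd,
        "de_down_prob": de_down_prob,
        "dropout": dropout, "dropout_midpoint": dropout_midpoint,
        "dropout_shape": dropout_shape, "doublet_rate": doublet_rate,
        "library_ln_mean": library_ln_mean, "library_ln_sd": library_ln_sd,
        "gene_mean": gene_mean, "gene_shape": gene_shape,
        "outlier_prob": outlier_prob, "outlier_ln_mean": outlier_ln_mean,
        "outlier_ln_sd": outlier_ln_sd, "activity_usage": list(activity_usage),
        "seed": seed,
        "designated_donors": [[int(d) for d in s] for s in donor_sets],
    }
    return SyntheticSC(
        counts=counts,
        cell_meta=meta,
        gep_matrix=pd.DataFrame(profiles, index=gene_ids, columns=prog_ids),
        usage=usage,
        params=params,
        library_sizes=lib,
        pre_dropout_counts=pre_dropout,
    )


def export_fixture(sim: SyntheticSC, path: str | Path) -> None:
    """Write a 10x-style plain-text fixture: counts.mtx, genes/barcodes TSVs,
    cell metadata, ground-truth GEP table and a params JSON.  Byte-identical
    given the same simulation."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(path / "counts.mtx", sparse.coo_matrix(sim.counts))
    pd.Series(sim.gep_matrix.index).to_csv(
        path / "genes.tsv", sep="\t", index=False, header=False
    )
    barcodes = [f"cell_{i:05d}" for i in range(sim.n_cells)]
    pd.Series(barcodes).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = sim.cell_meta.copy()
    meta.insert(0, "barcode", barcodes)
    meta.to_csv(path / "cell_meta.tsv", sep="\t", index=False)
    sim.gep_matrix.to_csv(path / "gep_truth.tsv", sep="\t")
    np.savetxt(path / "usage.tsv", sim.usage, delimiter="\t")
    with open(path / "params.json", "w") as fh:
        json.dump(sim.params, fh, indent=1)


def load_fixture(path: str | Path) -> SyntheticSC:
    path = Path(path)
    counts = np.asarray(spio.mmread(path / "counts.mtx").todense()).astype(np.int64)
    meta = pd.read_csv(path / "cell_meta.tsv", sep="\t").drop(columns=["barcode"])
    gep = pd.read_csv(path / "gep_truth.tsv", sep="\t", index_col=0)
    usage = np.loadtxt(path / "usage.tsv", delimiter="\t")
    with open(path / "params.json") as fh:
        params = json.load(fh)
    return SyntheticSC(counts, meta, gep, usage, params)


def to_cell_matrix(sim: SyntheticSC):
    """View the simulation as a :class:`~ziptf.pseudobulk.CellCountMatrix`
    (donor -> sample), optionally useful after dropping flagged doublets."""
    from .pseudobulk import CellCountMatrix

    meta = sim.cell_meta.rename(columns={"donor": "sample"})[
        ["sample", "cell_type", "is_doublet"]
    ]
    return CellCountMatrix(
        sim.counts.astype(float), meta, list(sim.gep_matrix.index)
    )
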