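"""Consensus aggregation across random restarts and rank-selection diagnostics.

Stochastic factorizations return different factor sets on every seeded run.
The consensus pipeline stabilizes them:

1. run the factorization M times with different seeds;
2. aggregate the mode-of-interest factor matrices, each normalized to unit
   Frobenius norm, into an ``I_k x (R*M)`` matrix;
3. K-means-cluster the aggregated columns with K = R and prune outlier
   columns per cluster with the Local Outlier Factor;
4. take the entrywise median of each cluster as the consensus factor;
5. refit the model using the consensus matrix as the initial guess for the
   mode of interest.

Rank selection combines explained variance of the fits, the cophenetic
correlation of the max-loading feature partition across runs, and the
silhouette of the column clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score as _sk_silhouette
from sklearn.neighbors import LocalOutlierFactor

from . import inference
from .inference import FitResult, ModelSpec
from .tensors import CountTensor, CPFactors, explained_variance, reconstruct

__all__ = [
    "RunEnsemble",
    "ConsensusModel",
    "RankSelectionReport",
    "aggregate_runs",
    "cluster_columns",
    "silhouette_score",
    "consensus_factor_matrix",
    "cophenetic_correlation",
    "refit_consensus",
    "run_ensemble",
    "select_rank",
]

OUTLIER = -1


@dataclass
class RunEnsemble:
    """M factorization results at a common rank; input to the consensus step."""

    runs: list[FitResult]
    rank: int
    mode_of_interest: int = -1

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("empty ensemble")
        shapes = {r.point_estimate.shape for r in self.runs}
        ranks = {r.point_estimate.rank for r in self.runs}
        if len(shapes) != 1 or len(ranks) != 1:
            raise ValueError("ensemble runs disagree on tensor shape or rank")
        if ranks.pop() != self.rank:
            raise ValueError("ensemble rank does not match runs")
        order = self.runs[0].point_estimate.order
        self.mode_of_interest %= order

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def factor_matrices(self) -> list[np.ndarray]:
        return [r.point_estimate.factors[self.mode_of_interest] for r in self.runs]


@dataclass
class ConsensusModel:
    """All intermediates of one consensus factorization."""

    aggregated: np.ndarray
    cluster_labels: np.ndarray  # per aggregated column; OUTLIER marks pruned
    silhouette: float
    consensus_factors: np.ndarray
    final_fit: FitResult
    mode_of_interest: int = -1


@dataclass
class RankSelectionReport:
    """Per-rank diagnostics and the smallest rank passing both thresholds."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    selected_rank: int | None = None
    ev_threshold: float = 0.9
    cophenetic_threshold: float = 0.9

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()


def aggregate_runs(ens: RunEnsemble) -> np.ndarray:
    """Concatenate each run's mode-of-interest factors, each block normalized
    to unit Frobenius norm: an ``I_k x (R*M)`` matrix."""
    blocks = []
    for m, mat in enumerate(ens.factor_matrices()):
        norm = float(np.linalg.norm(mat))
        if norm == 0:
            raise ValueError(f"run {m} has an all-zero factor matrix")
        blocks.append(mat / norm)
    return np.hstack(blocks)


def _unit_columns(agg: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(agg, axis=0, keepdims=True)
    return agg / np.where(norms > 0, norms, 1.0)


def cluster_columns(
    agg: np.ndarray,
    K: int,
    seed: int = 0,
    lof: bool = True,
    lof_contamination: float = 0.05,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """K-means over aggregated columns with per-cluster LOF outlier pruning.

    Returns ``(labels, retained)``: cluster labels per column (``OUTLIER`` for
    pruned ones) and a boolean retained mask.  Euclidean distance, 10
    restarts, seeded.  By default each column is rescaled to unit L2 norm
    first — CP component scales are arbitrary (a column's magnitude can
    migrate to the other modes), so only direction is meaningful.
    """
    if K < 2:
        raise ValueError("need at least 2 clusters")
    cols = _unit_columns(agg).T if normalize else agg.T
    if cols.shape[0] < K:
        raise ValueError(f"cannot form {K} clusters from {cols.shape[0]} columns")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    labels = km.fit_predict(cols)
    retained = np.ones(len(labels), dtype=bool)
    if lof:
        for c in range(K):
            idx = np.flatnonzero(labels == c)
            if len(idx) < 4:
                continue
            # size-1 neighbors would put every point in every neighborhood and
            # flatten the local densities LOF compares; leave one point out
            n_nb = min(20, len(idx) - 2)
            pred = LocalOutlierFactor(
                n_neighbors=n_nb, contamination=lof_contamination
            ).fit_predict(cols[idx])
            retained[idx[pred == -1]] = False
    out = labels.copy()
    out[~retained] = OUTLIER
    return out, retained


def silhouette_score(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette ``(b - a) / max(a, b)`` over points (rows).

    a is the mean intra-cluster distance and b the smallest mean distance to
    another cluster; Euclidean, consistent with the column clustering.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(_sk_silhouette(np.asarray(points, float), labels, metric="euclidean"))


def consensus_factor_matrix(
    agg: np.ndarray, labels: np.ndarray, rank: int | None = None
) -> np.ndarray:
    """Entrywise median of the retained columns of each cluster (``I_k x R``)."""
    labels = np.asarray(labels)
    clusters = sorted(c for c in np.unique(labels) if c != OUTLIER)
    if rank is not None and len(clusters) != rank:
        missing = sorted(set(range(rank)) - set(clusters))
        raise ValueError(f"clusters {missing} are empty after outlier pruning")
    cols = []
    for c in clusters:
        members = agg[:, labels == c]
        if members.shape[1] == 0:
            raise ValueError(f"cluster {c} is empty after outlier pruning")
        cols.append(np.median(members, axis=1))
    return np.column_stack(cols)


def cophenetic_correlation(
    ens: RunEnsemble, max_features: int = 2000, seed: int = 0
) -> float:
    """Stability of the max-loading feature partition across runs.

    Each feature (row of the mode-of-interest factor matrix) is assigned to
    its maximum-loading component per run; the average connectivity matrix
    over runs yields ``1 - connectivity`` distances, and the returned value is
    the cophenetic correlation between those distances and the dendrogram
    (average linkage) built from them.  1 means every run induces the same
    partition.  For large feature modes a seeded subsample of
    ``max_features`` features is used.
    """
    if ens.n_runs < 2:
        raise ValueError("cophenetic correlation needs at least 2 runs")
    mats = ens.factor_matrices()
    n_feat = mats[0].shape[0]
    if n_feat < 2:
        raise ValueError("need at least 2 features")
    idx = np.arange(n_feat)
    if n_feat > max_features:
        idx = np.random.default_rng(seed).choice(n_feat, max_features, replace=False)
        idx.sort()
    conn = np.zeros((len(idx), len(idx)))
    for mat in mats:
        # max loading taken on unit-norm columns: CP column scale is arbitrary
        assign = np.argmax(_unit_columns(mat)[idx], axis=1)
        conn += assign[:, None] == assign[None, :]
    conn /= ens.n_runs
    dist = 1.0 - conn
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        return 1.0  # all runs agree (or all disagree identically): no spread
    link = hierarchy.linkage(condensed, method="average")
    c, _ = hierarchy.cophenet(link, condensed)
    return float(c)


def run_ensemble(
    x: CountTensor,
    spec: ModelSpec,
    n_runs: int,
    seed: int = 0,
    mode_of_interest: int = -1,
    **fit_kwargs,
) -> RunEnsemble:
    """M independently seeded fits of ``x`` under ``spec``."""
    child = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    runs = [inference.fit(x, spec, seed=int(s), **fit_kwargs) for s in child]
    return RunEnsemble(runs, rank=spec.rank, mode_of_interest=mode_of_interest)


def refit_consensus(
    x: CountTensor,
    ens: RunEnsemble,
    spec: ModelSpec,
    seed: int = 0,
    lof: bool = True,
    freeze_init: bool = False,
    **fit_kwargs,
) -> ConsensusModel:
    """Aggregate -> cluster -> prune -> median -> refit: steps 2-5.

    The consensus matrix initializes the mode-of-interest variational means of
    a final fit (rescaled back to the data scale, since aggregation normalizes
    each run's block); the other modes restart from the prior under ``seed``.
    The final fit defaults to a larger budget than the ensemble members
    (max_iter 1500, 4 Monte-Carlo samples per step): the refit is one run and
    its convergence decides the quality of the whole consensus, so it gets
    the extra care.  Pass ``max_iter``/``n_mc_samples`` to override.
    """
    fit_kwargs.setdefault("max_iter", 1500)
    fit_kwargs.setdefault("n_mc_samples", 4)
    if ens.n_runs < 2:
        raise ValueError("consensus requires at least 2 runs")
    agg = aggregate_runs(ens)
    labels, _ = cluster_columns(agg, K=ens.rank, seed=seed, lof=lof)
    unit = _unit_columns(agg)
    sil = silhouette_score(unit.T[labels != OUTLIER], labels[labels != OUTLIER])
    cons = consensus_factor_matrix(unit, labels, rank=ens.rank)
    k = ens.mode_of_interest
    # Frobenius normalization in the aggregation discards the data scale; put
    # it back so the initial reconstruction (with the other modes at their
    # prior means) matches the mean of the data
    shp, rate = spec.mode_prior(x.order)
    other_prior_mean = float(
        np.prod([shp[m] / rate[m] for m in range(x.order) if m != k])
    )
    denom = other_prior_mean * float(cons.mean(axis=0).sum())
    scale = float(x.data.mean()) / max(denom, 1e-300)
    init_mat = cons * scale
    init_factors = [np.ones((d, ens.rank)) for d in x.shape]
    init_factors[k] = init_mat
    final = inference.fit(
        x,
        spec,
        seed=seed,
        init=CPFactors(init_factors),
        init_mode=k,
        freeze_init=freeze_init,
        **fit_kwargs,
    )
    return ConsensusModel(agg, labels, sil, cons, final, mode_of_interest=k)


def select_rank(
    x: CountTensor,
    ranks: list[int],
    M: int,
    spec: ModelSpec,
    seed: int = 0,
    ev_threshold: float = 0.9,
    cophenetic_threshold: float = 0.9,
    silhouette_range: tuple[int, int] | None = None,
    mode_of_interest: int = -1,
    **fit_kwargs,
) -> RankSelectionReport:
    """Rank scan: M seeded fits per rank with stability diagnostics.

    For each candidate rank the report records mean/sd explained variance,
    cophenetic correlation of the run ensemble, and a silhouette sweep over
    cluster counts of the aggregated columns (which K maximizes it, and the
    silhouette at K = rank).  The selected rank is the smallest one whose mean
    explained variance and cophenetic correlation both clear their thresholds
    (0.9 by default); if none qualifies a warning is issued and
    ``selected_rank`` is None.
    """
    if not ranks:
        raise ValueError("ranks must be non-empty")
    if M < 2:
        raise ValueError("rank selection needs M >= 2 runs per rank")
    ranks = sorted(ranks)
    rows = []
    root = np.random.SeedSequence(seed)
    for rank, sub in zip(ranks, root.spawn(len(ranks))):
        sub_seed = int(sub.generate_state(1)[0] % (2**31))
        r_spec = ModelSpec(**{**spec.__dict__, "rank": rank})
        ens = run_ensemble(
            x, r_spec, M, seed=sub_seed, mode_of_interest=mode_of_interest, **fit_kwargs
        )
        evs = [r.explained_variance for r in ens.runs]
        coph = cophenetic_correlation(ens, seed=sub_seed)
        agg = aggregate_runs(ens)
        lo, hi = silhouette_range or (2, min(rank + 4, agg.shape[1] - 1))
        hi = min(hi, agg.shape[1] - 1)
        unit = _unit_columns(agg)
        sil_at = {}
        for K in range(lo, hi + 1):
            labels, _ = cluster_columns(agg, K=K, seed=sub_seed, lof=False)
            sil_at[K] = silhouette_score(unit.T, labels)
        best_k = max(sil_at, key=sil_at.get)
        rows.append(
            {
                "rank": rank,
                "ev_mean": float(np.mean(evs)),
                "ev_sd": float(np.std(evs)),
                "cophenetic": coph,
                "silhouette_at_rank": sil_at.get(rank, np.nan),
                "silhouette_best_k": best_k,
                "silhouette_best": sil_at[best_k],
            }
        )
    records = pd.DataFrame(rows)
    ok = records[
        (records.ev_mean >= ev_threshold)
        & (records.cophenetic >= cophenetic_threshold)
    ]
    selected = int(ok["rank"].iloc[0]) if len(ok) else None
    if selected is None:
        warnings.warn(
            "no rank satisfies both the explained-variance and cophenetic "
            "thresholds; report returned without a selected rank",
            stacklevel=2,
        )
    return RankSelectionReport(records, selected, ev_threshold, cophenetic_threshold)
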