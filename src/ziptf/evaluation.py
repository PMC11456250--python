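"""Scoring recovered factors against ground-truth gene expression programs.

``align_factors`` builds the full Pearson correlation matrix between inferred
gene-mode factors and true program profiles and resolves a one-to-one
matching by optimal bipartite assignment; ``recovery_score`` aggregates the
matched mean correlation over repeated runs, and ``run_consistency`` measures
run-to-run similarity with the factorization cosine score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .inference import FitResult
from .tensors import cosine_score

__all__ = ["AlignmentResult", "align_factors", "recovery_score", "run_consistency"]


@dataclass
class AlignmentResult:
    """One-to-one factor-to-program matching and its correlations."""

    matching: list[tuple[int, int]]  # (factor column, truth column)
    per_pair_r: np.ndarray
    mean_r: float
    correlation_matrix: np.ndarray  # factors x programs


def _corr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlations between columns of a and b; constant columns 0."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    sa = np.sqrt((ac * ac).sum(axis=0))
    sb = np.sqrt((bc * bc).sum(axis=0))
    bad_a, bad_b = sa == 0, sb == 0
    if bad_a.any() or bad_b.any():
        warnings.warn(
            "constant column(s) encountered; their correlations set to 0",
            stacklevel=3,
        )
    denom = np.outer(np.where(bad_a, 1.0, sa), np.where(bad_b, 1.0, sb))
    c = (ac.T @ bc) / denom
    c[bad_a, :] = 0.0
    c[:, bad_b] = 0.0
    return c


def align_factors(gene_factors, truth) -> AlignmentResult:
    """Match inferred gene factors to true programs one-to-one by Pearson r.

    The assignment maximizes the total matched correlation (optimal bipartite
    matching over the factors x programs correlation matrix); ``mean_r`` is
    the average correlation of the matched pairs — the overall recovery
    accuracy of a factorization.  Extra factors or programs beyond ``min(R, P)`` remain
    unmatched.
    """
    gf = np.asarray(gene_factors, float)
    tr = truth.to_numpy() if isinstance(truth, pd.DataFrame) else np.asarray(truth, float)
    if gf.shape[0] != tr.shape[0]:
        raise ValueError(
            f"gene axes differ: {gf.shape[0]} factor rows vs {tr.shape[0]} truth rows"
        )
    corr = _corr_columns(gf, tr)
    rows, cols = linear_sum_assignment(corr, maximize=True)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    per_pair = corr[rows, cols]
    return AlignmentResult(pairs, per_pair, float(per_pair.mean()), corr)


def _gene_factor_matrix(run, gene_mode: int):
    if isinstance(run, FitResult):
        return run.point_estimate.factors[gene_mode]
    if hasattr(run, "factors"):
        return run.factors[gene_mode]
    return np.asarray(run, float)


def recovery_score(
    method_runs: list, truth, gene_mode: int = -1
) -> tuple[float, float, list[float]]:
    """Mean +/- sd of the aligned mean Pearson correlation over runs.

    Accepts FitResults, CPFactors or raw gene-factor matrices.  Returns
    ``(mean, sd, per-run scores)``.
    """
    if not method_runs:
        raise ValueError("need at least one run")
    scores = [
        align_factors(_gene_factor_matrix(r, gene_mode), truth).mean_r
        for r in method_runs
    ]
    return float(np.mean(scores)), float(np.std(scores)), scores


def run_consistency(runs: list[FitResult]) -> list[float]:
    """Cosine score for every unordered pair of runs (run-to-run stability)."""
    if len(runs) < 2:
        raise ValueError("consistency needs at least 2 runs")
    facs = [r.point_estimate if isinstance(r, FitResult) else r for r in runs]
    ranks = {f.rank for f in facs}
    if len(ranks) != 1:
        raise ValueError(f"runs disagree on rank: {sorted(ranks)}")
    return [float(cosine_score(a, b)) for a, b in combinations(facs, 2)]
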