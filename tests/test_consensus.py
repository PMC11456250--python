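"""Consensus aggregation, clustering, cophenetic and rank-selection units."""

import numpy as np
import pytest

from ziptf.consensus import (
    OUTLIER,
    RunEnsemble,
    aggregate_runs,
    cluster_columns,
    consensus_factor_matrix,
    cophenetic_correlation,
    silhouette_score,
)
from ziptf.inference import FitResult, ModelSpec, VariationalState
from ziptf.tensors import CPFactors


def _fake_fit(mats, rank) -> FitResult:
    """Wrap factor matrices as a FitResult without running inference."""
    factors = CPFactors(mats)
    state = VariationalState(
        [np.ones_like(m) for m in mats], [np.ones_like(m) for m in mats]
    )
    spec = ModelSpec("gamma_poisson", rank=rank)
    return FitResult(factors, state, spec, 0.0, 0, True, 0)


def _ensemble(gene_mats, rank):
    runs = [
        _fake_fit([np.ones((3, rank)), np.ones((4, rank)), g], rank)
        for g in gene_mats
    ]
    return RunEnsemble(runs, rank=rank, mode_of_interest=-1)


class TestAggregateRuns:
    def test_blocks_have_unit_norm_and_shape(self):
        rng = np.random.default_rng(0)
        ens = _ensemble([rng.random((10, 9)) for _ in range(20)], rank=9)
        agg = aggregate_runs(ens)
        assert agg.shape == (10, 180)
        for m in range(20):
            block = agg[:, m * 9 : (m + 1) * 9]
            assert np.linalg.norm(block) == pytest.approx(1.0, abs=1e-10)

    def test_single_run_is_normalized_matrix(self):
        rng = np.random.default_rng(1)
        mat = rng.random((6, 3))
        ens = _ensemble([mat], rank=3)
        assert np.allclose(aggregate_runs(ens), mat / np.linalg.norm(mat))

    def test_zero_norm_run_rejected(self):
        ens = _ensemble([np.zeros((5, 2)), np.ones((5, 2))], rank=2)
        with pytest.raises(ValueError, match="zero"):
            aggregate_runs(ens)


class TestClusterColumns:
    def test_duplicated_columns_recovered_exactly(self):
        rng = np.random.default_rng(2)
        u, v = rng.random(8), rng.random(8)
        agg = np.column_stack([u, u, u, v, v, v])
        labels, retained = cluster_columns(agg, K=2, seed=0, lof=False)
        assert retained.all()
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_far_column_flagged_as_outlier(self):
        u = np.array([1.0, 0, 0, 0])
        v = np.array([0, 1.0, 0, 0])
        cols = [u, 1.01 * u, 0.99 * u, v, 1.01 * v, 0.99 * v, 100 * (u + v)]
        agg = np.column_stack(cols)
        labels, retained = cluster_columns(
            agg, K=2, seed=0, lof=True, lof_contamination=0.2
        )
        assert not retained[6]
        assert labels[6] == OUTLIER

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        agg = np.repeat(rng.random((6, 3)), 4, axis=1) + 0.01 * rng.random((6, 12))
        labels, _ = cluster_columns(agg, K=3, seed=1, lof=False)
        perm = rng.permutation(12)
        labels_p, _ = cluster_columns(agg[:, perm], K=3, seed=1, lof=False)
        # same partition up to cluster relabeling
        for i in range(12):
            for j in range(12):
                same = labels[perm[i]] == labels[perm[j]]
                assert same == (labels_p[i] == labels_p[j])

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_columns(np.ones((4, 3)), K=5)


class TestSilhouette:
    def test_tight_separated_clusters(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.01, (20, 2))
        b = rng.normal(10, 0.01, (20, 2))
        pts = np.vstack([a, b])
        labels = np.array([0] * 20 + [1] * 20)
        assert silhouette_score(pts, labels) > 0.9

    def test_identical_points_within_clusters(self):
        pts = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        assert silhouette_score(pts, np.array([0, 0, 1, 1])) == pytest.approx(1.0)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_score(np.ones((4, 2)), np.zeros(4))


class TestConsensusMedian:
    def test_median_of_three(self):
        agg = np.array([[1.0, 1, 3, 0], [0, 0, 0, 5]])
        labels = np.array([0, 0, 0, 1])
        cons = consensus_factor_matrix(agg, labels)
        assert np.allclose(cons[:, 0], [1, 0])
        assert np.allclose(cons[:, 1], [0, 5])

    def test_entrywise_median(self):
        agg = np.array([[0.0, 4, 2], [2, 2, 8]])
        cons = consensus_factor_matrix(agg, np.zeros(3, dtype=int))
        assert np.allclose(cons[:, 0], [2, 2])

    def test_identical_columns_returned(self):
        col = np.array([1.0, 2, 3])
        agg = np.column_stack([col] * 4)
        cons = consensus_factor_matrix(agg, np.zeros(4, dtype=int))
        assert np.allclose(cons[:, 0], col)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        agg = rng.random((5, 8))
        labels = np.array([0, 1] * 4)
        base = consensus_factor_matrix(agg, labels)
        perm = rng.permutation(8)
        again = consensus_factor_matrix(agg[:, perm], labels[perm])
        assert np.allclose(base, again)

    def test_empty_cluster_errors(self):
        agg = np.ones((3, 2))
        with pytest.raises(ValueError, match="cluster"):
            consensus_factor_matrix(agg, np.array([0, 0]), rank=2)


class TestCopheneticCorrelation:
    def _ens_from_assignments(self, assigns, rank):
        """Build runs whose max-loading partition matches given assignments."""
        mats = []
        for a in assigns:
            m = np.full((len(a), rank), 0.1)
            m[np.arange(len(a)), a] = 1.0
            mats.append(m)
        return _ensemble(mats, rank)

    def test_identical_assignments_give_one(self):
        a = np.array([0, 0, 1, 1, 2, 2, 0, 1])
        ens = self._ens_from_assignments([a, a, a, a], rank=3)
        assert cophenetic_correlation(ens) == pytest.approx(1.0)

    def test_random_assignments_below_point_nine(self):
        rng = np.random.default_rng(6)
        assigns = [rng.integers(0, 3, 60) for _ in range(8)]
        ens = self._ens_from_assignments(assigns, rank=3)
        assert cophenetic_correlation(ens) < 0.9

    def test_invariant_to_column_permutation(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 3, 30)
        mats = []
        for _ in range(4):
            m = np.full((30, 3), 0.1)
            m[np.arange(30), a] = 1.0
            mats.append(m[:, rng.permutation(3)])
        ens = _ensemble(mats, 3)
        assert cophenetic_correlation(ens) == pytest.approx(1.0)

    def test_monotone_decrease_under_label_noise(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 3, 100)
        vals = []
        for noise in (0.0, 0.2, 0.5):
            assigns = []
            for _ in range(6):
                a = base.copy()
                flip = rng.random(100) < noise
                a[flip] = rng.integers(0, 3, int(flip.sum()))
                assigns.append(a)
            vals.append(cophenetic_correlation(self._ens_from_assignments(assigns, 3)))
        assert vals[0] == pytest.approx(1.0)
        assert vals[0] > vals[1] > vals[2]

    def test_needs_two_runs(self):
        ens = self._ens_from_assignments([np.array([0, 1, 0, 1])], rank=2)
        with pytest.raises(ValueError):
            cophenetic_correlation(ens)
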