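import itertools

import numpy as np
import pytest

from calseg import CostScheme, pairwise_matrix, pam, quality_metrics, select_k, silhouette
from calseg.clustering import ClusterSolution
from calseg.distance import DissimilarityMatrix


def matrix_from_values(values, weights=None):
    values = np.asarray(values, dtype=np.float64)
    u = values.shape[0]
    w = np.ones(u) if weights is None else np.asarray(weights, dtype=np.float64)
    return DissimilarityMatrix(
        values=values,
        agg_weights=w,
        index=np.arange(u),
        unique_states=np.tile(np.arange(u, dtype=np.int8)[:, None], (1, 59)) % 5,
        costs=CostScheme.constant(),
    )


def random_matrix(rng, u):
    pts = rng.random((u, 2)) * 10
    return np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))


def brute_force_objective(values, w, k):
    u = values.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(u), k):
        obj = float(np.sum(w * values[:, medoids].min(axis=1)))
        best = min(best, obj)
    return best


class TestPAM:
    def test_k_equals_u_zero_objective(self):
        vals = random_matrix(np.random.default_rng(0), 5)
        m = matrix_from_values(vals)
        sol = pam(m, 5)
        assert sol.objective == 0.0
        assert sorted(sol.medoids) == list(range(5))
        assert all(sol.assignment[m] == i for i, m in enumerate(sol.medoids))

    def test_two_tight_pairs(self):
        vals = np.array(
            [
                [0.0, 0.1, 10.0, 10.0],
                [0.1, 0.0, 10.0, 10.0],
                [10.0, 10.0, 0.0, 0.1],
                [10.0, 10.0, 0.1, 0.0],
            ]
        )
        sol = pam(matrix_from_values(vals), 2)
        assert {tuple(sorted(sol.assignment[:2])), tuple(sorted(sol.assignment[2:]))} \
            == {(0, 0), (1, 1)}
        assert sol.objective == pytest.approx(0.2)

    def test_k_out_of_range(self):
        m = matrix_from_values(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            pam(m, 4)

    def test_matches_exhaustive_optimum_100_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            u = int(rng.integers(3, 9))
            k = int(rng.integers(1, min(3, u - 1) + 1))
            vals = random_matrix(rng, u)
            w = rng.random(u) + 0.1
            m = matrix_from_values(vals, w)
            sol = pam(m, k)
            assert sol.objective == pytest.approx(
                brute_force_objective(vals, w, k), rel=1e-9
            ), f"trial {trial}: u={u} k={k}"

    def test_duplicated_observations_equal_doubled_weights(self, rng):
        seqs = rng.integers(0, 5, size=(15, 59)).astype(np.int8)
        w = rng.random(15) + 0.2
        m_dup = pairwise_matrix(np.vstack([seqs, seqs]), np.concatenate([w, w]))
        m_wtd = pairwise_matrix(seqs, 2 * w)
        for k in (2, 4):
            assert pam(m_dup, k).objective == pytest.approx(
                pam(m_wtd, k).objective
            )

    def test_deterministic(self, small_run):
        a = pam(small_run["dissim"], 6)
        b = pam(small_run["dissim"], 6)
        assert (a.medoids == b.medoids).all()
        assert (a.assignment == b.assignment).all()


class TestSilhouette:
    def test_hand_computed_four_point_fixture(self):
        # clusters {0,1} and {2,3}; widths worked out by hand
        vals = np.array(
            [
                [0.0, 1.0, 4.0, 5.0],
                [1.0, 0.0, 6.0, 3.0],
                [4.0, 6.0, 0.0, 1.0],
                [5.0, 3.0, 1.0, 0.0],
            ]
        )
        sol = ClusterSolution(k=2, medoids=np.array([0, 2]),
                              assignment=np.array([0, 0, 1, 1]),
                              objective=2.0, iterations=0)
        s = silhouette(matrix_from_values(vals), sol)
        np.testing.assert_allclose(s, [7 / 9, 7 / 9, 4 / 5, 3 / 4])

    def test_perfectly_separated_clusters(self):
        vals = np.array(
            [
                [0.0, 0.0, 1.0, 1.0],
                [0.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.0],
                [1.0, 1.0, 0.0, 0.0],
            ]
        )
        sol = ClusterSolution(k=2, medoids=np.array([0, 2]),
                              assignment=np.array([0, 0, 1, 1]),
                              objective=0.0, iterations=0)
        s = silhouette(matrix_from_values(vals), sol)
        np.testing.assert_allclose(s, 1.0)

    def test_equidistant_point_scores_zero(self):
        vals = np.array(
            [
                [0.0, 1.0, 2.0, 2.0],
                [1.0, 0.0, 1.0, 1.0],   # point 1: a == b == 1
                [2.0, 1.0, 0.0, 1.0],
                [2.0, 1.0, 1.0, 0.0],
            ]
        )
        sol = ClusterSolution(k=2, medoids=np.array([0, 2]),
                              assignment=np.array([0, 0, 1, 1]),
                              objective=0.0, iterations=0)
        s = silhouette(matrix_from_values(vals), sol)
        assert s[1] == pytest.approx(0.0)

    def test_requires_k_at_least_two(self):
        sol = ClusterSolution(k=1, medoids=np.array([0]),
                              assignment=np.zeros(3, dtype=int),
                              objective=0.0, iterations=0)
        with pytest.raises(ValueError):
            silhouette(matrix_from_values(np.zeros((3, 3))), sol)


class TestQualityMetrics:
    def two_blob_solution(self, rng, u=60, sep=20.0):
        half = u // 2
        pts = np.concatenate([rng.normal(0, 1, half), rng.normal(sep, 1, u - half)])
        vals = np.abs(pts[:, None] - pts[None, :])
        sol = ClusterSolution(
            k=2, medoids=np.array([0, half]),
            assignment=np.array([0] * half + [1] * (u - half)),
            objective=0.0, iterations=0,
        )
        return matrix_from_values(vals), sol

    def test_near_perfect_separation(self, rng):
        m, sol = self.two_blob_solution(rng, sep=100.0)
        asw, pbc, hg = quality_metrics(m, sol)
        assert asw > 0.95 and pbc > 0.95 and hg == pytest.approx(1.0)

    def test_random_assignment_near_zero(self, rng):
        vals = random_matrix(rng, 100)
        sol = ClusterSolution(
            k=2, medoids=np.array([0, 1]),
            assignment=rng.integers(0, 2, 100),
            objective=0.0, iterations=0,
        )
        sol.assignment[0], sol.assignment[1] = 0, 1
        asw, pbc, hg = quality_metrics(matrix_from_values(vals), sol)
        assert abs(asw) < 0.1 and abs(pbc) < 0.1 and abs(hg) < 0.1

    def test_pbc_equals_direct_correlation_on_fixture(self, rng):
        vals = random_matrix(rng, 5)
        sol = ClusterSolution(k=2, medoids=np.array([0, 3]),
                              assignment=np.array([0, 0, 0, 1, 1]),
                              objective=0.0, iterations=0)
        _, pbc, _ = quality_metrics(matrix_from_values(vals), sol)
        iu, ju = np.triu_indices(5, k=1)
        d = vals[iu, ju]
        y = (sol.assignment[iu] != sol.assignment[ju]).astype(float)
        assert pbc == pytest.approx(np.corrcoef(d, y)[0, 1])

    def test_hubert_gamma_against_pair_enumeration(self, rng):
        vals = random_matrix(rng, 8)
        w = rng.random(8) + 0.5
        sol = ClusterSolution(k=2, medoids=np.array([0, 4]),
                              assignment=np.array([0, 0, 0, 0, 1, 1, 1, 1]),
                              objective=0.0, iterations=0)
        _, _, hg = quality_metrics(matrix_from_values(vals, w), sol)
        iu, ju = np.triu_indices(8, k=1)
        d = vals[iu, ju]
        same = sol.assignment[iu] == sol.assignment[ju]
        pw = (w[iu] * w[ju])
        s_plus = s_minus = 0.0
        for i in np.flatnonzero(same):
            for j in np.flatnonzero(~same):
                if d[i] < d[j]:
                    s_plus += pw[i] * pw[j]
                elif d[i] > d[j]:
                    s_minus += pw[i] * pw[j]
        assert hg == pytest.approx((s_plus - s_minus) / (s_plus + s_minus))

    def test_weight_scale_invariance(self, small_run):
        m = small_run["dissim"]
        sol = pam(m, 4)
        base = quality_metrics(m, sol)
        import dataclasses

        scaled = dataclasses.replace(m, agg_weights=m.agg_weights * 1000.0)
        np.testing.assert_allclose(quality_metrics(scaled, sol), base)

    def test_degenerate_matrix_warns_and_zeroes(self):
        vals = np.full((4, 4), 3.0)
        np.fill_diagonal(vals, 0.0)
        sol = ClusterSolution(k=2, medoids=np.array([0, 2]),
                              assignment=np.array([0, 0, 1, 1]),
                              objective=0.0, iterations=0)
        with pytest.warns(UserWarning, match="degenerate"):
            _, pbc, hg = quality_metrics(matrix_from_values(vals), sol)
        assert pbc == 0.0 and hg == 0.0


class TestSelectK:
    def test_one_row_per_k(self, small_run):
        rep = select_k(small_run["dissim"], range(2, 6))
        assert list(rep.table["k"]) == [2, 3, 4, 5]

    def test_degenerate_abstains(self):
        vals = np.full((5, 5), 2.0)
        np.fill_diagonal(vals, 0.0)
        with pytest.warns(UserWarning):
            rep = select_k(matrix_from_values(vals), [2, 3])
        assert rep.selected_k is None

    def test_single_unique_sequence_abstains(self):
        m = pairwise_matrix([np.zeros(59, dtype=np.int8)] * 4)
        with pytest.warns(UserWarning):
            rep = select_k(m, [2])
        assert rep.selected_k is None

    def test_empty_range_rejected(self, small_run):
        with pytest.raises(ValueError):
            select_k(small_run["dissim"], [])
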