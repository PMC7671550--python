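"""Fuzzy k-medoids / k-means algorithms against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fclustfd.clustering import (
    FuzzyKMeans,
    FuzzyKMedoids,
    fkm,
    fkmed,
    global_oracle_fkmed,
    objective,
    update_medoids,
    update_memberships,
)
from fclustfd.simulate import generate_coefficient_blobs
from fclustfd.validity import adjusted_rand_index


class TestUpdateMedoids:
    def test_weighted_cost_argmin_one_dimension(self):
        # units at 0, 1, 5 all in one cluster: costs 26, 17, 41 -> medoid is 1
        C = np.array([[0.0], [1.0], [5.0]])
        U = np.ones((3, 1))
        assert update_medoids(C, U, f=1.0 + 1e-9)[0] == 1

    def test_single_member_cluster_keeps_its_unit(self):
        C = np.array([[0.0], [4.0], [9.0]])
        U = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        medoids = update_medoids(C, U, f=1.5)
        assert medoids[0] == 0

    def test_uniform_memberships_give_global_medoid(self):
        rng = np.random.default_rng(5)
        C = rng.standard_normal((9, 3))
        U = np.full((9, 1), 1.0)
        (medoid,) = update_medoids(C, U, f=2.0)
        costs = ((C[:, None, :] - C[None, :, :]) ** 2).sum(-1).sum(1)
        assert medoid == np.argmin(costs)

    def test_collisions_resolved_to_distinct_medoids(self):
        # two identical clusters of memberships force the same argmin
        C = np.array([[0.0], [0.1], [10.0], [10.1]])
        U = np.full((4, 2), 0.5)
        medoids = update_medoids(C, U, f=1.5)
        assert len(set(medoids.tolist())) == 2


class TestUpdateMemberships:
    def test_equal_distances_split_evenly(self):
        C = np.array([[0.0], [2.0], [1.0]])
        U = update_memberships(C, [0, 1], f=1.5)
        np.testing.assert_allclose(U[2], [0.5, 0.5])

    def test_medoid_rows_are_crisp(self):
        C = np.array([[0.0], [2.0], [1.0]])
        U = update_memberships(C, [0, 1], f=1.5)
        np.testing.assert_array_equal(U[0], [1.0, 0.0])
        np.testing.assert_array_equal(U[1], [0.0, 1.0])

    def test_f2_closed_form(self):
        # f = 2 with squared distances (1, 3) -> memberships (0.75, 0.25)
        C = np.array([[0.0], [1.0 + np.sqrt(3)], [1.0]])
        U = update_memberships(C, [0, 1], f=2.0)
        np.testing.assert_allclose(U[2], [0.75, 0.25])

    def test_duplicate_medoids_rejected(self):
        with pytest.raises(ValueError):
            update_memberships(np.zeros((3, 1)), [1, 1], f=1.5)


class TestObjective:
    def test_hard_single_cluster_total_dispersion(self):
        C = np.array([[0.0], [1.0], [3.0]])
        U = np.ones((3, 1))
        assert objective(C, U, [1], f=1.5) == pytest.approx(1.0 + 0.0 + 4.0)

    def test_identical_units_zero(self):
        C = np.zeros((4, 2))
        U = np.full((4, 2), 0.5)
        assert objective(C, U, [0, 1], f=1.5) == 0.0

    def test_matches_direct_recomputation(self, rng):
        C = rng.standard_normal((8, 3))
        medoids = [0, 5]
        U = update_memberships(C, medoids, f=1.5)
        direct = sum(
            U[i, l] ** 1.5 * np.sum((C[i] - C[m]) ** 2)
            for i in range(8)
            for l, m in enumerate(medoids)
        )
        assert objective(C, U, medoids, f=1.5) == pytest.approx(direct)


class TestFkmed:
    def test_recovers_separated_clouds(self, blobs_2d):
        C, labels = blobs_2d
        part = fkmed(C, 2, seed=0)
        assert adjusted_rand_index(part.labels, labels) == 1.0
        assert part.converged

    def test_duplicate_groups_become_crisp(self):
        C = np.repeat([[0.0, 0.0], [5.0, 5.0]], 3, axis=0)
        part = fkmed(C, 2, seed=1)
        assert part.objective == pytest.approx(0.0, abs=1e-12)
        assert set(np.round(part.membership.ravel()).tolist()) <= {0.0, 1.0}
        # one medoid per duplicate group
        assert sorted(C[part.medoid_indices][:, 0].tolist()) == [0.0, 5.0]

    def test_matches_enumeration_oracle(self):
        C, _ = generate_coefficient_blobs(6, [[0, 0, 0], [3, 3, 3]], 1.0, seed=11)
        part = fkmed(C, 2, n_starts=30, seed=3)
        *_, oracle_obj = global_oracle_fkmed(C, 2, 1.5)
        assert part.objective == pytest.approx(oracle_obj, rel=1e-10)

    def test_invalid_parameters(self, blobs_2d):
        C, _ = blobs_2d
        with pytest.raises(ValueError):
            fkmed(C, k=len(C), seed=0)
        with pytest.raises(ValueError):
            fkmed(C, 2, f=1.0, seed=0)

    def test_objective_nonincreasing_within_every_start(self, rng):
        C = rng.standard_normal((30, 4))
        est = FuzzyKMedoids(n_clusters=3, n_starts=10, random_state=7).fit(C)
        for history in est.objective_histories_:
            diffs = np.diff(history)
            assert (diffs <= 1e-10).all()

    def test_fuzziness_limits(self, blobs_2d):
        C, labels = blobs_2d
        # f -> 1: essentially hard; matches the well-separated truth
        hard = fkmed(C, 2, f=1.01, seed=0)
        assert np.minimum(hard.membership, 1 - hard.membership).max() < 1e-6
        assert adjusted_rand_index(hard.labels, labels) == 1.0
        # f large: memberships flatten toward 1/k (distance-concentrated data)
        rng = np.random.default_rng(0)
        C_hi = rng.standard_normal((20, 100))
        flat = fkmed(C_hi, 2, f=20.0, seed=0)
        nonmed = np.setdiff1d(np.arange(20), flat.medoid_indices)
        assert np.abs(flat.membership[nonmed] - 0.5).max() < 0.02

    def test_unit_permutation_equivariance(self, blobs_2d):
        C, _ = blobs_2d
        perm = np.random.default_rng(9).permutation(len(C))
        a = fkmed(C, 2, n_starts=30, seed=0)
        b = fkmed(C[perm], 2, n_starts=30, seed=0)
        assert a.objective == pytest.approx(b.objective, rel=1e-9)
        # medoids map through the permutation (up to cluster relabeling)
        assert set(perm[b.medoid_indices].tolist()) == set(a.medoid_indices.tolist())

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_membership_simplex_property(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.standard_normal((12, 3))
        est = FuzzyKMedoids(n_clusters=3, n_starts=3, random_state=seed % 997).fit(C)
        U = est.membership_
        assert (U >= 0).all() and (U <= 1).all()
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-10)
        for l, i in enumerate(est.medoid_indices_):
            assert U[i, l] == 1.0


class TestFkm:
    def test_single_cluster_centroid_is_mean(self, rng):
        C = rng.standard_normal((10, 3))
        est = FuzzyKMeans(n_clusters=2, n_starts=5, random_state=0).fit(C)
        # weighted-mean identity: recompute centroids from U
        W = est.membership_**est.fuzziness
        H = (W.T @ C) / W.sum(axis=0)[:, None]
        np.testing.assert_allclose(est.cluster_centers_, H, atol=1e-6)

    def test_agrees_with_fkmed_on_separated_data(self, blobs_2d):
        C, labels = blobs_2d
        part = fkm(C, 2, seed=0)
        assert adjusted_rand_index(part.labels, labels) == 1.0

    def test_symmetric_pair_centroids_converge_to_points(self):
        C = np.array([[-1.0, 0.0], [1.0, 0.0]] * 3)
        part = fkm(C, 2, f=1.5, seed=0)
        centers = np.sort(part.centroids[:, 0])
        np.testing.assert_allclose(centers, [-1.0, 1.0], atol=1e-4)


class TestGlobalOracle:
    def test_hand_enumeration_colinear(self):
        # units at 0, 1, 5, 6 with k=2: optimal medoid pair must split {0,1} | {5,6}
        C = np.array([[0.0], [1.0], [5.0], [6.0]])
        medoids, U, obj = global_oracle_fkmed(C, 2, f=1.5)
        assert set(C[medoids][:, 0].tolist()) in ({0.0, 5.0}, {0.0, 6.0}, {1.0, 5.0}, {1.0, 6.0})
        assert {medoids[0] < 2, medoids[1] < 2} == {True, False}
        # crisp assignment cost is an upper bound attained at f -> 1; obj below it
        assert obj <= 1.0 + 1.0 + 1e-9

    def test_n_equals_k_is_zero(self):
        C = np.random.default_rng(0).standard_normal((3, 2))
        *_, obj = global_oracle_fkmed(C, 3, f=1.5)
        assert obj == 0.0

    def test_duplicate_rows_tie_invariant(self):
        C = np.array([[0.0], [0.0], [4.0], [4.0]])
        *_, obj = global_oracle_fkmed(C, 2, f=1.5)
        assert obj == pytest.approx(0.0, abs=1e-12)

    def test_large_instance_rejected(self):
        with pytest.raises(ValueError):
            global_oracle_fkmed(np.zeros((16, 2)), 2, f=1.5)
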