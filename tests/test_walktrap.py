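import numpy as np
import pytest

from carousel.walktrap import (
    allocate_budget,
    cell_distance,
    community_distance,
    merge_cost,
    transition_matrix,
    walk_probabilities,
    walktrap_partition,
)
from walktrap_oracle import brute_walktrap, random_connected_graph


def two_triangles_bridge():
    """Two unit-weight triangles {0,1,2} and {3,4,5} joined by edge 2-3."""
    U = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
        U[a, b] = U[b, a] = 1.0
    return U


class TestTransition:
    def test_two_node_swap(self):
        M = transition_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(M.P.toarray(), [[0, 1], [1, 0]])

    def test_star_row_split(self):
        U = np.array([[0, 2, 2], [2, 0, 0], [2, 0, 0]], dtype=float)
        M = transition_matrix(U)
        np.testing.assert_allclose(M.P.toarray()[0], [0, 0.5, 0.5])

    def test_weighted_triangle_rows_are_row_normalized(self):
        U = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        M = transition_matrix(U)
        np.testing.assert_allclose(M.P.toarray(), U / U.sum(axis=1)[:, None])
        np.testing.assert_allclose(np.asarray(M.P.sum(axis=1)).ravel(), 1, atol=1e-10)

    def test_zero_degree_rejected(self):
        U = np.zeros((3, 3))
        U[0, 1] = U[1, 0] = 1
        with pytest.raises(ValueError, match="zero-degree"):
            transition_matrix(U)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            transition_matrix(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestWalkProbabilities:
    def test_l1_is_p_itself(self):
        U = two_triangles_bridge()
        M = transition_matrix(U, l=1)
        np.testing.assert_allclose(walk_probabilities(M), M.P.toarray())

    def test_two_node_length2_walk_returns_home(self):
        M = transition_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]), l=2)
        np.testing.assert_allclose(walk_probabilities(M), np.eye(2), atol=1e-15)

    def test_path_graph_matches_explicit_square(self):
        U = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        M = transition_matrix(U, l=2)
        P = M.P.toarray()
        np.testing.assert_allclose(walk_probabilities(M), P @ P, atol=1e-15)
        np.testing.assert_allclose(walk_probabilities(M).sum(axis=1), 1, atol=1e-12)


class TestDistances:
    def test_identical_walk_rows_zero_distance(self):
        # vertices 1 and 2 of the star are exchangeable
        U = np.array([[0, 2, 2], [2, 0, 0], [2, 0, 0]], dtype=float)
        M = transition_matrix(U, l=2)
        assert cell_distance(M, 1, 2) == pytest.approx(0, abs=1e-14)

    def test_sum_form_equals_norm_form(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            U = random_connected_graph(rng, n_max=9)
            M = transition_matrix(U, l=4)
            Pl = walk_probabilities(M)
            a, b = 0, 1
            sum_form = np.sqrt((((Pl[a] - Pl[b]) ** 2) / M.d).sum())
            assert cell_distance(M, a, b, Pl) == pytest.approx(sum_form, abs=1e-12)

    def test_path_endpoints_match_brute_force(self):
        U = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        M = transition_matrix(U, l=2)
        d = U.sum(axis=1)
        P = U / d[:, None]
        Pl = P @ P
        expected = np.sqrt((((Pl[0] - Pl[2]) ** 2) / d).sum())
        assert cell_distance(M, 0, 2) == pytest.approx(expected, abs=1e-14)

    def test_singleton_community_reduces_to_cell_distance(self):
        rng = np.random.default_rng(9)
        U = random_connected_graph(rng, n_max=8)
        M = transition_matrix(U, l=4)
        assert community_distance(M, [0], [2]) == pytest.approx(
            cell_distance(M, 0, 2), abs=1e-14
        )

    def test_identical_communities_zero(self):
        U = two_triangles_bridge()
        M = transition_matrix(U, l=3)
        assert community_distance(M, [0, 1], [0, 1]) == pytest.approx(0, abs=1e-14)

    def test_four_cycle_community_distance_brute_force(self):
        U = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            U[a, b] = U[b, a] = 1.0
        M = transition_matrix(U, l=2)
        d = U.sum(axis=1)
        Pl = np.linalg.matrix_power(U / d[:, None], 2)
        r1 = Pl[[0, 1]].mean(axis=0)
        r2 = Pl[[2, 3]].mean(axis=0)
        expected = np.sqrt((((r1 - r2) ** 2) / d).sum())
        assert community_distance(M, [0, 1], [2, 3]) == pytest.approx(expected, abs=1e-14)


class TestMergeCost:
    def test_singletons_ward_form(self):
        rng = np.random.default_rng(10)
        U = random_connected_graph(rng, n_max=8)
        n = U.shape[0]
        M = transition_matrix(U, l=4)
        r = cell_distance(M, 0, 1)
        assert merge_cost(M, [0], [1]) == pytest.approx(r**2 / (2 * n), abs=1e-12)

    def test_nonnegative_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            U = random_connected_graph(rng, n_max=10)
            M = transition_matrix(U, l=4)
            n = U.shape[0]
            idx = rng.permutation(n)
            Y1, Y2 = list(idx[: n // 2]), list(idx[n // 2 :])
            assert merge_cost(M, Y1, Y2) >= -1e-12

    def test_within_triangle_cheaper_than_across(self):
        U = two_triangles_bridge()
        M = transition_matrix(U, l=4)
        assert merge_cost(M, [0], [1]) < merge_cost(M, [0], [3])

    def test_overlap_rejected(self):
        U = two_triangles_bridge()
        M = transition_matrix(U, l=4)
        with pytest.raises(ValueError, match="overlap"):
            merge_cost(M, [0, 1], [1, 2])


class TestPartition:
    def test_complete_graph_single_community(self):
        n = 6
        U = np.ones((n, n)) - np.eye(n)
        part = walktrap_partition(U, target_k=1)
        assert part.n_communities == 1
        assert set(part.assignment) == {0}

    def test_target_n_all_singletons(self):
        U = two_triangles_bridge()
        part = walktrap_partition(U, target_k=6)
        assert part.n_communities == 6
        assert part.merge_history == []

    def test_two_cliques_bridge_recovered(self):
        n = 8
        U = np.zeros((n, n))
        for grp in (range(4), range(4, 8)):
            for a in grp:
                for b in grp:
                    if a != b:
                        U[a, b] = 1.0
        U[3, 4] = U[4, 3] = 1.0
        part = walktrap_partition(U, target_k=2)
        assert part.n_communities == 2
        assert len(set(part.assignment[:4])) == 1
        assert len(set(part.assignment[4:])) == 1
        assert part.assignment[0] != part.assignment[7]

    def test_merge_costs_recorded_nonnegative(self):
        rng = np.random.default_rng(12)
        U = random_connected_graph(rng, n_max=12)
        part = walktrap_partition(U, target_k=2)
        assert all(ds >= -1e-12 for _, _, ds in part.merge_history)

    def test_disconnected_components_get_proportional_budget(self):
        # components of sizes 6 and 3; budget 3 -> 2 + 1
        U = np.zeros((9, 9))
        for grp in (range(6), range(6, 9)):
            g = list(grp)
            for a, b in zip(g, g[1:]):
                U[a, b] = U[b, a] = 1.0
        part = walktrap_partition(U, target_k=3)
        assert part.n_communities == 3
        comps = [set(part.assignment[:6]), set(part.assignment[6:])]
        assert len(comps[0]) == 2 and len(comps[1]) == 1

    def test_target_below_component_count_rejected(self):
        U = np.zeros((4, 4))
        U[0, 1] = U[1, 0] = 1.0
        U[2, 3] = U[3, 2] = 1.0
        with pytest.raises(ValueError, match="components"):
            walktrap_partition(U, target_k=1)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        U = random_connected_graph(rng, n_max=10)
        n = U.shape[0]
        part = walktrap_partition(U, target_k=3)
        perm = rng.permutation(n)
        Up = U[np.ix_(perm, perm)]
        part_p = walktrap_partition(Up, target_k=3)
        # partitions agree as set systems after undoing the permutation
        orig = {frozenset(np.flatnonzero(part.assignment == k)) for k in range(3)}
        back = {
            frozenset(perm[np.flatnonzero(part_p.assignment == k)]) for k in range(3)
        }
        assert orig == back

    def test_sigma_increases_by_delta_sigma_per_merge(self):
        """Total within-community dispersion grows by exactly the recorded cost."""
        rng = np.random.default_rng(14)
        for _ in range(5):
            U = random_connected_graph(rng, n_max=10)
            n = U.shape[0]
            M = transition_matrix(U, l=4)
            Pl = walk_probabilities(M)
            phi = Pl / np.sqrt(M.d)

            def sigma(comms):
                tot = 0.0
                for Y in comms.values():
                    mu = phi[Y].mean(axis=0)
                    tot += ((phi[Y] - mu) ** 2).sum()
                return tot / n

            part = walktrap_partition(U, target_k=1)
            comms = {i: [i] for i in range(n)}
            prev = sigma(comms)
            for r1, r2, dsig in part.merge_history:
                comms[r1] = comms[r1] + comms[r2]
                del comms[r2]
                cur = sigma(comms)
                assert cur - prev == pytest.approx(dsig, abs=1e-10)
                prev = cur


class TestBudget:
    @pytest.mark.parametrize(
        "sizes, k, expected",
        [([6, 3], 3, [2, 1]), ([10], 4, [4]), ([5, 5], 2, [1, 1]), ([8, 1, 1], 5, [3, 1, 1])],
    )
    def test_largest_remainder(self, sizes, k, expected):
        assert allocate_budget(sizes, k) == expected

    def test_every_component_at_least_one(self):
        alloc = allocate_budget([100, 1, 1], 3)
        assert alloc == [1, 1, 1]


def test_oracle_equivalence_sample():
    """Optimized merge sequence matches the definitional brute force."""
    rng = np.random.default_rng(21)
    for _ in range(25):
        U = random_connected_graph(rng, n_max=10)
        hist_o, _ = brute_walktrap(U, 1)
        part = walktrap_partition(U, target_k=1)
        assert [(a, b) for a, b, _ in hist_o] == [(a, b) for a, b, _ in part.merge_history]
        for (_, _, x), (_, _, y) in zip(hist_o, part.merge_history):
            assert x == pytest.approx(y, abs=1e-10)
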