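import numpy as np
import pytest

from delmap.cost import path_cost
from delmap.matrix import DeletionMatrix
from delmap.simulate import SimulationSpec, generate, shuffle_markers
from delmap.solver import (
    SearchCeilingError,
    SearchItem,
    collapse_order,
    map_pipeline,
    profile_groups,
    refine_within_cluster,
    solve_exact,
)
from delmap.clustering import MarkerCluster

from conftest import brute_force_solve, brute_path_cost, random_matrix


class TestSolveExact:
    def test_three_marker_hand_case(self, tiny_matrix):
        cost, orders = solve_exact(tiny_matrix, "any")
        assert cost == 1
        assert set(orders) == {("A", "C", "B"), ("C", "A", "B")}

    def test_degenerate_all_present(self):
        m = DeletionMatrix(("x",), ("A", "B", "C"), np.ones((1, 3), dtype=int))
        cost, orders = solve_exact(m, "any")
        assert cost == 0
        assert len(orders) == 6  # every permutation ties
        (group,) = profile_groups(m)
        assert set(group) == {"A", "B", "C"}

    @pytest.mark.parametrize("opt", ["any", "del"])
    def test_matches_brute_force_enumeration(self, opt, rng):
        """Branch and bound returns exactly the brute-force optimum set."""
        for _ in range(60):
            m = random_matrix(rng, int(rng.integers(1, 9)), int(rng.integers(2, 7)))
            expected_cost, expected_orders = brute_force_solve(m, opt)
            cost, orders = solve_exact(m, opt)
            assert cost == expected_cost
            assert set(orders) == expected_orders

    def test_ceiling_exceeded_is_advisory_error(self, rng):
        m = random_matrix(rng, 3, 6)
        with pytest.raises(SearchCeilingError, match="clusters"):
            solve_exact(m, "any", ceiling=5)

    def test_slack_returns_near_optimal_superset(self, rng):
        m = random_matrix(rng, 5, 5)
        cost0, tight = solve_exact(m, "any")
        cost2, loose = solve_exact(m, "any", slack=2)
        assert cost0 == cost2
        assert set(tight) <= set(loose)
        assert all(path_cost(m, o, "any").total <= cost0 + 2 for o in loose)

    def test_marker_input_order_never_changes_cost(self, rng):
        m = random_matrix(rng, 5, 6)
        cost, orders = solve_exact(m, "any")
        sh = shuffle_markers(m, rng)
        cost_sh, orders_sh = solve_exact(sh, "any")
        assert cost == cost_sh
        assert set(orders) == set(orders_sh)


class TestRefineWithinCluster:
    def test_singleton_cluster_trivial(self, rng):
        m = random_matrix(rng, 3, 4)
        cluster = MarkerCluster("c", (m.marker_names[0],))
        _, orders = refine_within_cluster(
            m, cluster, np.ones(3, dtype=bool), None, "any"
        )
        assert orders == [(m.marker_names[0],)]

    def test_identical_profiles_tie_both_ways(self):
        m = DeletionMatrix(("x", "y"), ("A", "B", "C"), np.array([[1, 1, 0], [0, 0, 1]]))
        cluster = MarkerCluster("c", ("A", "B"))
        right = SearchItem("r", m.column("C").astype(np.int64), 1)
        cost, orders = refine_within_cluster(m, cluster, np.ones(2, dtype=bool), right, "any")
        assert set(orders) == {("A", "B"), ("B", "A")}

    def test_flanked_search_matches_flanked_brute_force(self):
        # one mutant, members X=1, Y=0, Z=1 between a fully-present left
        # context and an all-deleted right virtual marker
        from itertools import permutations

        m = DeletionMatrix(("mu",), ("X", "Y", "Z"), np.array([[1, 0, 1]]))
        right = SearchItem("r", np.array([0]), 1)
        cost, orders = refine_within_cluster(
            m, MarkerCluster("c", ("X", "Y", "Z")), np.ones(1, dtype=bool), right, "any"
        )

        def flanked_cost(perm):
            seq = [1] + [int(m.states[0, m.marker_names.index(p)]) for p in perm] + [0]
            return sum(a != b for a, b in zip(seq, seq[1:]))

        best = min(flanked_cost(p) for p in permutations(m.marker_names))
        assert cost == best
        assert set(orders) == {
            p for p in permutations(m.marker_names) if flanked_cost(p) == best
        }


class TestMapPipeline:
    def test_singleton_clustering_equals_raw_exact(self, rng):
        """With n = Ma the pipeline reduces to plain exact solving."""
        for _ in range(20):
            m = random_matrix(rng, int(rng.integers(2, 7)), int(rng.integers(2, 7)))
            cost, orders = solve_exact(m, "any")
            sol = map_pipeline(m, n=m.n_markers, opt="any")
            assert sol.best_cost == cost
            groups = sol.profile_groups
            assert {collapse_order(o, groups) for o in sol.best_orders} == {
                collapse_order(o, groups) for o in orders
            }

    def test_pipeline_never_beats_exact_search(self, rng):
        # like-for-like: smoothing off, since the corrected matrix scores
        # differently from the raw one the exact search sees
        for _ in range(20):
            m = random_matrix(rng, 4, int(rng.integers(4, 8)))
            cost, _ = solve_exact(m, "any")
            sol = map_pipeline(m, n=2, opt="any", smooth=False)
            assert sol.best_cost >= cost

    def test_best_orders_rescore_to_best_cost(self, rng):
        m, _ = generate(SimulationSpec(30, 10, 60, seed=5))
        sh = shuffle_markers(m, rng)
        sol = map_pipeline(sh, n=6, opt="any", smooth=False)
        assert sol.best_orders
        assert sol.n_best_maps == len(sol.best_orders) >= 1
        for order in sol.best_orders:
            assert path_cost(m, order, "any").total == sol.best_cost

    def test_best_orders_rescore_on_corrected_matrix_when_smoothing(self, rng):
        from delmap.clustering import apply_smoothing, cluster_markers

        m, _ = generate(SimulationSpec(30, 10, 70, n_pcr_errors=5, seed=6))
        sh = shuffle_markers(m, rng)
        sol = map_pipeline(sh, n=6, opt="any", smooth=True)
        corrected = apply_smoothing(sh, cluster_markers(sh, 6))
        for order in sol.best_orders:
            assert path_cost(corrected, order, "any").total == sol.best_cost

    def test_paper_scale_panel_completes(self):
        m, _ = generate(SimulationSpec(71, 41, 442, seed=11))
        sol = map_pipeline(m, n=12, opt="any")
        assert sol.best_cost > 0
        assert sol.n_best_maps >= 1

    def test_profile_group_members_mutually_costless(self, rng):
        m, _ = generate(SimulationSpec(20, 8, 40, seed=3))
        for g in profile_groups(m):
            for a in g:
                for b in g:
                    assert np.array_equal(m.column(a), m.column(b))
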