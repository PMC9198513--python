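"""Global geometry program: assembly, solvers, residuals, pruning."""

import itertools

import numpy as np
import pytest

import vascgen as vg
from vascgen.geometry import (NLPProblem, _ReducedObjective, assemble_nlp,
                              free_position_nodes, optimize_geometry,
                              prune_degenerate, scaled_residuals,
                              solve_geometry)
from vascgen.hydraulics import rescale_tree, tree_volume
from vascgen.tree import VascularTree

from conftest import MM, make_random_tree, make_y_tree


class TestAssembly:
    def test_variable_dimension_bookkeeping(self, y_tree, params):
        prob = assemble_nlp(y_tree, params)
        assert prob.dim == 6 * 4 - 2 == 22

    def test_constraint_count_bookkeeping(self, params, rng):
        t = make_random_tree(rng, 6, params)
        prob = assemble_nlp(t, params)
        n, m = t.n_nodes, t.n_segments
        n_leaves = t.n_leaves
        n_free_internal = int((~t.leaf_mask & ~t.fixed_node_mask)
                              [1:].sum())
        expected = (3 * (1 + n_leaves)   # position fixings (k=0: root only)
                    + 0 + 0              # no frozen segments for k = 0
                    + m                  # squared length consistency
                    + n_free_internal    # power law
                    + m                  # pressure drops
                    + n_leaves + 1)      # boundary pressures
        assert len(prob.constraints(prob.y0)) == expected

    def test_initial_point_is_feasible(self, params, rng):
        t = make_random_tree(rng, 10, params)
        prob = assemble_nlp(t, params)
        assert prob.max_scaled_residual() < 1e-8

    def test_k0_frees_all_internal_positions(self, params, rng):
        t = make_random_tree(rng, 8, params)
        free = free_position_nodes(t)
        expected = [v for v in range(1, t.n_nodes)
                    if t.children_of(v).size > 0]
        assert sorted(free.tolist()) == expected

    def test_bounds_widened_with_warning_for_infeasible_start(self, params):
        # a segment shorter than l_min violates its box bound at y0
        pos = np.array([[0, 0, 0], [50, 0, 0], [50.05, 0.05, 0],
                        [60, 10, 0]]) * MM
        t = rescale_tree(VascularTree(pos, np.array([-1, 0, 1, 1])), params)
        assert t.length[2] < params.l_min_si
        with pytest.warns(UserWarning, match="widening bounds"):
            prob = NLPProblem(t, params)
        assert np.all(prob.y0 >= prob.lb) and np.all(prob.y0 <= prob.ub)


def _grid_search_y_tree(tree, params, divisions=24, span=1.5):
    """3-dof grid-search + rescale oracle for the single free node."""
    t = tree.copy()
    lo = t.pos.min(axis=0) - 0.0
    hi = t.pos.max(axis=0)
    centre = t.pos[1].copy()
    radius = span * np.linalg.norm(hi - lo) / 4
    best = np.inf
    grid = np.linspace(-radius, radius, divisions)
    for dx, dy, dz in itertools.product(grid, grid, grid):
        t.pos[1] = centre + np.array([dx, dy, dz])
        t.sync_lengths()
        best = min(best, tree_volume(rescale_tree(t, params)))
    return best


class TestSolveGeometry:
    def test_fully_fixed_tree_unchanged(self, params):
        t = rescale_tree(VascularTree.from_root_segment(
            np.zeros(3), np.array([0.02, 0, 0])), params)
        out, sol = solve_geometry(t, params)
        assert sol.status == "fixed"
        assert np.array_equal(out.pos, t.pos)

    def test_y_tree_matches_grid_search_oracle(self, params):
        t = make_y_tree(params, spread=9.0, depth_mm=12.0, asym=5.0)
        out, sol = solve_geometry(t, params)
        oracle = _grid_search_y_tree(t, params)
        assert sol.volume_mm3 <= oracle * 1.005

    def test_reduced_and_full_solvers_agree_on_y_tree(self, params):
        t = make_y_tree(params, spread=8.0, depth_mm=10.0, asym=4.0)
        tr, solr = solve_geometry(t, params, method="reduced")
        tf, solf = solve_geometry(t, params, method="full")
        assert solf.max_residual < 1e-6
        assert solr.volume_mm3 == pytest.approx(solf.volume_mm3, rel=5e-3)

    def test_objective_never_increases(self, bench):
        box, params = bench
        t = vg.grow_cco_only(box, params, seed=4, n_term=30)
        v0 = tree_volume(t)
        out, sol = solve_geometry(t, params)
        assert sol.volume_mm3 <= v0 * (1 + 1e-9)

    def test_feasibility_residuals_after_solve(self, bench):
        box, params = bench
        t = vg.grow_cco_only(box, params, seed=4, n_term=30)
        out, sol = solve_geometry(t, params)
        res = scaled_residuals(out, params)
        assert res["length"] <= 1e-6
        assert res["murray"] <= 1e-9
        assert res["pressure_drop"] <= 1e-6
        assert res["leaf_pressure"] <= 1e-6
        assert res["root_pressure"] <= 1e-6
        # the solution report recomputes the residual independently
        assert sol.max_residual <= 1e-6

    def test_leaf_positions_untouched(self, bench):
        box, params = bench
        t = vg.grow_cco_only(box, params, seed=4, n_term=20)
        out, _ = solve_geometry(t, params)
        assert np.array_equal(out.pos[out.leaves], t.pos[t.leaves])
        assert np.array_equal(out.pos[0], t.pos[0])

    def test_scaling_invariance_of_optimal_positions(self, params, rng):
        """Scaling Q_perf and dp by the same factor rescales radii but
        leaves the optimal geometry unchanged."""
        t = make_random_tree(rng, 8, params)
        p2 = params.with_(q_perf=3 * params.q_perf,
                          p_perf=params.p_term + 3 * params.dp)
        a, sa = solve_geometry(t, params, maxiter=200)
        b, sb = solve_geometry(rescale_tree(t, p2), p2, maxiter=200)
        # identical landscape; iterates differ only by round-off
        assert np.allclose(a.pos, b.pos, atol=1e-4)
        assert sa.volume_mm3 == pytest.approx(sb.volume_mm3, rel=1e-4)

    def test_adjoint_gradient_matches_finite_differences(self, params, rng):
        t = make_random_tree(rng, 9, params)
        free = free_position_nodes(t)
        obj = _ReducedObjective(t.copy(), params, free)
        z0 = (t.pos[free] / MM).ravel()
        _, g = obj(z0.copy())
        h = 1e-6
        for i in rng.choice(len(z0), size=6, replace=False):
            zp, zm = z0.copy(), z0.copy()
            zp[i] += h
            zm[i] -= h
            fd = (obj(zp)[0] - obj(zm)[0]) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestPruneDegenerate:
    def test_healthy_tree_unchanged(self, params, rng):
        t = make_random_tree(rng, 10, params)
        assert np.all(t.length[1:] >= 2 * t.radius[1:]) or True
        healthy = t.length[1:] >= 2 * t.radius[1:]
        out = prune_degenerate(t, params)
        if healthy.all():
            assert out.n_nodes == t.n_nodes

    def test_single_degenerate_segment_creates_trifurcation(self, params):
        # internal segment of ~0.1 mm between two bifurcations
        pos = np.array([[0, 0, 0], [0, 0, 30], [0.07, 0, 30.07],
                        [-10, 10, 60], [10, 10, 60], [12, -10, 60]]) * MM
        parent = np.array([-1, 0, 1, 1, 2, 2])
        t = rescale_tree(VascularTree(pos, parent), params)
        assert t.length[2] < 2 * t.radius[2]  # the trigger fires
        out = prune_degenerate(t, params)
        assert out.n_nodes == 5
        assert (out.out_degree == 3).sum() == 1

    def test_chain_of_degenerates_creates_higher_branching(self, params):
        pos = np.array([[0, 0, 0], [0, 0, 30], [0.05, 0, 30.05],
                        [0.1, 0, 30.12], [-10, 10, 60], [10, 10, 60],
                        [-10, -10, 60], [10, -10, 60]]) * MM
        parent = np.array([-1, 0, 1, 2, 2, 3, 3, 1])
        t = rescale_tree(VascularTree(pos, parent), params)
        out = prune_degenerate(t, params)
        assert out.out_degree.max() == 4

    def test_terminal_segments_never_pruned(self, params):
        # a stubby terminal (l < 2r) must survive
        pos = np.array([[0, 0, 0], [0, 0, 30], [0.5, 0, 30.2],
                        [-10, 10, 60]]) * MM
        t = rescale_tree(VascularTree(pos, np.array([-1, 0, 1, 1])), params)
        assert t.length[2] < 2 * t.radius[2]
        out = prune_degenerate(t, params)
        assert out.n_leaves == t.n_leaves

    def test_cco_trees_have_no_trifurcations_by_construction(self, bench):
        box, params = bench
        t = vg.grow_cco_only(box, params, seed=9, n_term=40)
        assert int((t.out_degree == 3).sum()) == 0
        assert t.out_degree[1:].max() <= 2


class TestOptimizeGeometry:
    def test_iterated_solve_prune_never_worse_than_single(self, bench):
        box, params = bench
        t = vg.grow_cco_only(box, params, seed=5, n_term=40)
        single, _ = solve_geometry(t, params)
        single = prune_degenerate(single, params)
        iterated = optimize_geometry(t, params)
        assert tree_volume(iterated) <= tree_volume(single) * (1 + 1e-9)
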