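"""Topology search: Catalan counting, swap enumeration, SA acceptance,
and the annealing loop against an exhaustive toy-scale oracle."""

import numpy as np
import pytest

import vascgen as vg
from vascgen.geometry import solve_geometry
from vascgen.hydraulics import rescale_tree, tree_volume
from vascgen.topology import (calibrate_t0, catalan, enumerate_swaps,
                              optimize_topology, sa_accept)
from vascgen.tree import VascularTree

from conftest import make_random_tree


class TestCatalan:
    def test_base_cases(self):
        assert catalan(0) == 1
        assert catalan(1) == 1

    def test_against_recurrence_oracle(self):
        # C_{n+1} = sum_i C_i C_{n-i}
        c = [1]
        for n in range(12):
            c.append(sum(c[i] * c[n - i] for i in range(n + 1)))
        for n in range(13):
            assert catalan(n) == c[n]

    def test_shape_enumeration_oracle(self):
        """C_3 = 5: binary tree shapes with 3 internal nodes, counted by
        brute-force generation via sequential leaf insertion."""
        # rooted ordered shapes with n internal nodes = C_n; enumerate via
        # the recurrence on (left, right) subtree sizes
        def shapes(n):
            if n == 0:
                return 1
            return sum(shapes(i) * shapes(n - 1 - i) for i in range(n))
        assert shapes(3) == 5 == catalan(3)
        assert catalan(10) == 16796

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            catalan(-1)


def enumerate_swaps_oracle(tree, params):
    """Brute-force double loops with the same feasibility filters, for both
    move kinds (node re-attachment and segment-interior splice)."""
    out = []

    def descendants(v):
        acc = {v}
        stack = [v]
        while stack:
            u = stack.pop()
            for c in tree.children_of(u):
                acc.add(int(c))
                stack.append(int(c))
        return acc

    for v in range(1, tree.n_nodes):
        if tree.fixed_segment_mask[v]:
            continue
        u = int(tree.parent[v])
        if tree.children_of(u).size < 2:
            continue
        sub = descendants(v)
        for w in range(1, tree.n_nodes):
            if w == u or w in sub or tree.fixed_node_mask[w]:
                continue
            if tree.children_of(w).size == 0:
                continue
            if np.linalg.norm(tree.pos[w] - tree.pos[v]) >= 2 * tree.length[v]:
                continue
            out.append(("node", v, w))
        if u == 0 or tree.children_of(u).size != 2 or tree.fixed_node_mask[u]:
            continue
        sibling = int(tree.children_of(u)[tree.children_of(u) != v][0])
        for t in range(1, tree.n_nodes):
            if tree.fixed_segment_mask[t] or t in sub or t in (u, sibling):
                continue
            mid = 0.5 * (tree.pos[t] + tree.pos[tree.parent[t]])
            if np.linalg.norm(mid - tree.pos[v]) >= 2 * tree.length[v]:
                continue
            out.append(("segment", v, t))
    return sorted(out)


class TestEnumerateSwaps:
    def test_y_tree_has_no_legal_swap(self, y_tree, params):
        assert enumerate_swaps(y_tree, params) == []

    def test_cycle_filter_excludes_descendants(self, params, rng):
        t = make_random_tree(rng, 12, params)
        tin, tout = t.euler_intervals()
        for m in enumerate_swaps(t, params):
            # the new parent never lies inside the moved subtree
            assert not (tin[m.seg] <= tin[m.new_parent] < tout[m.seg])

    def test_matches_brute_force_oracle(self, params):
        rng = np.random.default_rng(17)
        for n_leaves in (5, 10, 20, 40):
            t = make_random_tree(rng, n_leaves, params)
            got = sorted((m.kind, m.seg, m.new_parent)
                         for m in enumerate_swaps(t, params))
            assert got == enumerate_swaps_oracle(t, params)

    def test_old_parent_keeps_a_child(self, params, rng):
        t = make_random_tree(rng, 15, params)
        for m in enumerate_swaps(t, params):
            u = t.parent[m.seg]
            assert t.children_of(u).size >= 2


class TestSAAccept:
    def test_zero_delta_always_accepted(self, rng):
        assert sa_accept(0.0, 1.0, rng)
        assert sa_accept(-5.0, 1e-9, rng)

    def test_acceptance_frequency_at_delta_equals_t(self):
        rng = np.random.default_rng(123)
        n = 100_000
        acc = sum(sa_accept(1.0, 1.0, rng) for _ in range(n)) / n
        assert acc == pytest.approx(np.exp(-1.0), abs=0.01)

    def test_vanishing_tail(self):
        rng = np.random.default_rng(7)
        acc = sum(sa_accept(100.0, 1.0, rng) for _ in range(2000))
        assert acc == 0

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            sa_accept(1.0, 0.0, rng)


def _all_binary_topologies(leaf_pos, root_pos):
    """Every rooted binary shape over the labelled leaves ((2n-3)!! of
    them), generated by sequential insertion of each leaf into every
    existing segment."""
    n = len(leaf_pos)
    base = [(np.array([-1, 0]), [root_pos, leaf_pos[0]])]
    for k in range(1, n):
        nxt = []
        for parent, pos in base:
            for seg in range(1, len(parent)):
                p2 = np.concatenate([parent, [parent[seg], len(parent)]])
                p2[seg] = len(parent)
                mid = 0.5 * (np.asarray(pos[seg])
                             + np.asarray(pos[parent[seg]]))
                nxt.append((p2, pos + [mid, leaf_pos[k]]))
        base = nxt
    return base


class TestOptimizeTopology:
    def test_zero_iterations_returns_input_volume(self, params, rng):
        t = make_random_tree(rng, 8, params)
        p = params.with_(sa_params=vg.SAParameters(iterations=0))
        out = optimize_topology(t, p, rng)
        assert tree_volume(out) <= tree_volume(t) * (1 + 1e-9)

    def test_greedy_limit_is_monotone(self, params):
        """At T ~ 0 only improving moves are accepted."""
        t = make_random_tree(np.random.default_rng(3), 15, params)
        p = params.with_(sa_params=vg.SAParameters(t0=1e-12, iterations=150))
        trace = []
        out = optimize_topology(t, p, np.random.default_rng(4), trace=trace)
        best = [row[3] for row in trace]
        assert all(a >= b - 1e-12 for a, b in zip(best, best[1:]))
        assert tree_volume(out) <= tree_volume(t)

    def test_best_so_far_non_increasing(self, params):
        t = make_random_tree(np.random.default_rng(6), 12, params)
        p = params.with_(sa_params=vg.SAParameters(iterations=120))
        trace = []
        optimize_topology(t, p, np.random.default_rng(8), trace=trace)
        best = [row[3] for row in trace]
        assert all(a >= b - 1e-12 for a, b in zip(best, best[1:]))

    def test_leaf_positions_bit_identical(self, bench):
        box, params = bench
        t = vg.grow_cco_only(box, params, seed=12, n_term=15)
        p = params.with_(sa_params=vg.SAParameters(iterations=150))
        out = optimize_topology(t, p, np.random.default_rng(2))
        a = np.sort(t.pos[t.leaves], axis=0)
        b = np.sort(out.pos[out.leaves], axis=0)
        assert np.array_equal(a, b)
        assert np.array_equal(t.pos[0], out.pos[0])

    def test_intermediate_trees_valid_after_moves(self, params):
        t = make_random_tree(np.random.default_rng(9), 10, params)
        p = params.with_(sa_params=vg.SAParameters(iterations=60))
        out = optimize_topology(t, p, np.random.default_rng(10))
        out.validate()
        res = vg.scaled_residuals(rescale_tree(out, params), params)
        assert res["murray"] <= 1e-9

    def test_finds_exhaustive_optimum_on_five_leaves(self, bench):
        """SA reaches the best volume over all 105 binary shapes with the
        same five (fixed) leaves in at least 9 of 10 seeded runs."""
        box, params = bench
        rng = np.random.default_rng(31)
        leaf_pos = [box.sample_uniform(rng, 1)[0] for _ in range(5)]
        root = np.zeros(3)
        best_oracle = np.inf
        for parent, pos in _all_binary_topologies(leaf_pos, root):
            t = VascularTree(np.array(pos), np.array(parent))
            t = rescale_tree(t, params)
            t, _ = solve_geometry(t, params, maxiter=300)
            best_oracle = min(best_oracle, tree_volume(t))
        # grow a CCO tree on the same terminals by sequential connection
        start = VascularTree(np.array([root, leaf_pos[0]]), np.array([-1, 0]))
        start = rescale_tree(start, params)
        from vascgen.growth import connect_terminal, optimize_bifurcation
        for x in leaf_pos[1:]:
            cands = []
            for seg in range(1, start.n_nodes):
                trial = connect_terminal(start, seg, x, params)
                optimize_bifurcation(trial, start.n_nodes, params)
                cands.append((tree_volume(trial), seg, trial))
            start = min(cands, key=lambda c: (c[0], c[1]))[2]
        hits = 0
        p = params.with_(sa_params=vg.SAParameters(iterations=500))
        for seed in range(10):
            out = optimize_topology(start, p, np.random.default_rng(100 + seed))
            if tree_volume(out) <= best_oracle * 1.005:
                hits += 1
        assert hits >= 9


class TestCalibration:
    def test_t0_positive_and_finite(self, params):
        t = make_random_tree(np.random.default_rng(13), 15, params)
        t0 = calibrate_t0(t, params, np.random.default_rng(14))
        assert 0 < t0 < np.inf
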