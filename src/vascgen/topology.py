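"""Discrete topology optimization by simulated-annealing subtree swaps.

The space of rooted binary topologies grows with the Catalan numbers, so an
exhaustive search is hopeless beyond toy sizes.  Instead, candidate moves
re-attach a segment (with its entire subtree) to a different internal node.
Moves are filtered: re-attachment below the moved subtree would create a
cycle, the new segment must not start out longer than twice the current
one (such swaps almost never improve the tree), and the frozen root subtree
is untouchable.  Each trial topology is geometry-optimized (a cheap local
solve freeing only nodes near the swap, with periodic full solves) and the
volume change is accepted or rejected by the Metropolis rule
p = exp(-delta_f / T) under a geometrically cooled temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, exp, log

import numpy as np

from .geometry import optimize_geometry, solve_geometry
from .hydraulics import rescale_tree, tree_volume
from .parameters import ModelParameters
from .tree import VascularTree


def catalan(n: int) -> int:
    """Catalan number C_n = binom(2n, n) / (n + 1), exact."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return comb(2 * n, n) // (n + 1)


@dataclass
class SwapMove:
    """Re-attach segment ``seg`` (the subtree rooted at its distal node
    moves with it).

    ``kind == "node"``: the new parent becomes the existing internal node
    ``new_parent``.  ``kind == "segment"``: the old bifurcation node is
    spliced out of its current position and re-inserted to split the
    segment whose distal node is ``new_parent`` (the classic exchange of a
    proximal point from one parent segment to another; requires the old
    parent to be a plain bifurcation)."""

    seg: int
    new_parent: int
    kind: str = "node"
    delta: float | None = None  # volume change (mm^3) after trial geometry


@dataclass
class AnnealingState:
    temperature: float
    iteration: int = 0
    current_volume: float = np.inf
    best_volume: float = np.inf
    accepted: int = 0
    rejected_streak: int = 0
    history: list = field(default_factory=list)


def enumerate_swaps(tree: VascularTree, params: ModelParameters) -> list[SwapMove]:
    """All feasible (segment, new-parent) moves.

    Filters: the new parent must be an internal node outside the moved
    subtree and outside the frozen root subtree (and not the root node or
    the current parent); the old parent must retain at least one child; the
    initial new segment |x_w - x_v| must be shorter than twice the current
    segment length.
    """
    n = tree.n_nodes
    if n < 4:
        return []
    outdeg = tree.out_degree
    tin, tout = tree.euler_intervals()
    fixed = tree.fixed_node_mask
    fixed_seg = tree.fixed_segment_mask
    segs = np.arange(1, n)
    out: list[SwapMove] = []

    # (a) re-attachment under an existing internal node
    movable = segs[(outdeg[tree.parent[segs]] >= 2) & ~fixed_seg[segs]]
    targets = np.flatnonzero((outdeg > 0) & ~fixed & (np.arange(n) != 0))
    if movable.size and targets.size:
        # subtree test: w in subtree(v) iff tin[v] <= tin[w] < tout[v]
        in_subtree = (tin[targets][None, :] >= tin[movable][:, None]) \
            & (tin[targets][None, :] < tout[movable][:, None])
        same = targets[None, :] == tree.parent[movable][:, None]
        dist = np.linalg.norm(tree.pos[targets][None, :, :]
                              - tree.pos[movable][:, None, :], axis=2)
        ok = ~in_subtree & ~same & (dist < 2.0 * tree.length[movable][:, None])
        iv, iw = np.nonzero(ok)
        out.extend(SwapMove(int(movable[i]), int(targets[j]))
                   for i, j in zip(iv, iw))

    # (b) splice the parent bifurcation into another segment's interior
    par = tree.parent[segs]
    mov = segs[(outdeg[par] == 2) & ~fixed_seg[segs] & ~fixed[par]
               & (par != 0)]
    if mov.size:
        u = tree.parent[mov]
        ptr, idx = tree.children
        sib = np.array([int(c[c != v][0])
                        for v, c in ((v, idx[ptr[uu]:ptr[uu + 1]])
                                     for v, uu in zip(mov, u))])
        tgt = segs[~fixed_seg[segs]]
        in_subtree = (tin[tgt][None, :] >= tin[mov][:, None]) \
            & (tin[tgt][None, :] < tout[mov][:, None])
        banned = (tgt[None, :] == u[:, None]) | (tgt[None, :] == sib[:, None])
        mid = 0.5 * (tree.pos[tgt] + tree.pos[tree.parent[tgt]])
        dist = np.linalg.norm(mid[None, :, :] - tree.pos[mov][:, None, :],
                              axis=2)
        ok = ~in_subtree & ~banned & (dist < 2.0 * tree.length[mov][:, None])
        iv, iw = np.nonzero(ok)
        out.extend(SwapMove(int(mov[i]), int(tgt[j]), kind="segment")
                   for i, j in zip(iv, iw))
    return out


def sa_accept(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis acceptance: always for improvements, else with
    probability exp(-delta / T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta <= 0:
        return True
    return bool(rng.random() < exp(-delta / temperature))


def _local_free_nodes(tree: VascularTree, seeds: list[int], radius: int) -> np.ndarray:
    """Free (internal, unfrozen) nodes within graph distance ``radius`` of
    the seed nodes, on the undirected tree."""
    ptr, idx = tree.children
    dist = np.full(tree.n_nodes, -1)
    frontier = [s for s in seeds if 0 <= s < tree.n_nodes]
    for s in frontier:
        dist[s] = 0
    for _ in range(radius):
        nxt = []
        for u in frontier:
            nbrs = list(idx[ptr[u]:ptr[u + 1]])
            if u != 0:
                nbrs.append(tree.parent[u])
            for v in nbrs:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    near = dist >= 0
    return np.flatnonzero(near & ~tree.fixed_node_mask & ~tree.leaf_mask
                          & (np.arange(tree.n_nodes) != 0))


def _trial_volume(tree: VascularTree, move: SwapMove, params: ModelParameters,
                  local_radius: int, maxiter: int) -> tuple[VascularTree, float]:
    old_parent = int(tree.parent[move.seg])
    if move.kind == "segment":
        trial = tree.splice_reattach(move.seg, move.new_parent)
    else:
        trial = tree.reattach(move.seg, move.new_parent)
    free = _local_free_nodes(trial, [move.seg, old_parent, move.new_parent],
                             local_radius)
    if free.size:
        trial, _ = solve_geometry(trial, params, free_nodes=free, maxiter=maxiter)
    else:
        trial = rescale_tree(trial, params, inplace=True)
    return trial, tree_volume(trial)


def calibrate_t0(tree: VascularTree, params: ModelParameters,
                 rng: np.random.Generator, probes: int = 100) -> float:
    """Initial temperature from probe moves: the median |delta_f| is
    accepted with probability one half."""
    moves = enumerate_swaps(tree, params)
    if not moves:
        return 1e-12
    vol = tree_volume(rescale_tree(tree, params))
    deltas = []
    for k in rng.choice(len(moves), size=min(probes, len(moves)), replace=False):
        _, v = _trial_volume(tree, moves[int(k)], params,
                             params.sa_params.local_radius, maxiter=10)
        deltas.append(abs(v - vol))
    med = float(np.median(deltas)) if deltas else 0.0
    return max(med / log(2.0), 1e-12)


def optimize_topology(tree: VascularTree, params: ModelParameters,
                      rng: np.random.Generator,
                      trace: list | None = None) -> VascularTree:
    """Simulated-annealing search over subtree swaps.

    Each iteration draws a uniform feasible move, geometry-optimizes the
    trial locally, and accepts by the Metropolis rule; the move list is
    re-enumerated after every accepted move and a full geometry solve runs
    every ``full_solve_every`` accepted moves.  When the best volume
    stagnates for ``reheat_after`` iterations the temperature is reset
    (standard reheating, to climb over multi-move barriers).  Returns the
    best tree encountered (never worse than the input).
    """
    sa = params.sa_params
    current = rescale_tree(tree, params)
    cur_vol = tree_volume(current)
    best, best_vol = current, cur_vol
    t0 = sa.t0 if sa.t0 is not None else calibrate_t0(current, params, rng)
    state = AnnealingState(temperature=t0, current_volume=cur_vol,
                           best_volume=best_vol)
    moves = enumerate_swaps(current, params)
    reheat_after = sa.reheat_after
    if reheat_after is None:
        reheat_after = max(50, sa.iterations // 8)
    since_full = 0
    since_best = 0
    n_reheats = 0
    for it in range(sa.iterations):
        state.iteration = it
        if not moves:
            break
        move = moves[int(rng.integers(len(moves)))]
        trial, vol = _trial_volume(current, move, params, sa.local_radius,
                                   maxiter=20)
        move.delta = vol - cur_vol
        if sa_accept(move.delta, state.temperature, rng):
            current, cur_vol = trial, vol
            state.accepted += 1
            state.rejected_streak = 0
            since_full += 1
            if since_full >= sa.full_solve_every:
                current, _ = solve_geometry(current, params)
                cur_vol = tree_volume(current)
                since_full = 0
            if cur_vol < best_vol - 1e-12:
                best, best_vol = current, cur_vol
                since_best = 0
            moves = enumerate_swaps(current, params)
        else:
            state.rejected_streak += 1
        state.current_volume = cur_vol
        state.best_volume = best_vol
        if trace is not None:
            trace.append((it, state.temperature, cur_vol, best_vol,
                          state.rejected_streak == 0))
        state.temperature *= sa.cooling
        since_best += 1
        if since_best >= reheat_after:
            level = sa.reheat_level * 0.5 ** n_reheats
            n_reheats += 1
            state.temperature = max(state.temperature, level * t0)
            current, cur_vol = best, best_vol
            moves = enumerate_swaps(current, params)
            since_best = 0
        if state.rejected_streak >= sa.max_consecutive_rejections:
            break
    # final full geometry polish (with pruning) of the best tree found
    polished = optimize_geometry(best, params)
    if tree_volume(polished) < best_vol:
        best = polished
    return best
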