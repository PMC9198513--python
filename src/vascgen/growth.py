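"""Constrained constructive optimization (CCO) growth.

The tree is grown one terminal at a time.  Each step samples an admissible
terminal point, tentatively connects it to each of the ``n_con`` nearest
segments by splitting the segment at a new bifurcation, locally optimizes
the bifurcation position for minimum total tree volume (with radii re-solved
hydraulically at every trial position), and commits the connection with the
lowest volume.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .domain import (GrowthError, PerfusionDomain, distances_to_tree,
                     sample_terminal_point, threshold_schedule)
from .hydraulics import rescale_tree, tree_volume_si
from .parameters import ModelParameters
from .tree import VascularTree


def nearest_segments(tree: VascularTree, x: np.ndarray, n_con: int) -> np.ndarray:
    """Ids of the min(n_con, |A|) segments closest to ``x``, ascending by
    distance; ties broken by segment creation index (older first)."""
    if tree.n_segments == 0:
        raise ValueError("tree has no segments")
    d = distances_to_tree(x, tree)
    ids = np.arange(1, tree.n_nodes)
    order = np.lexsort((ids, d))
    return ids[order][:min(n_con, ids.size)]


def connect_terminal(tree: VascularTree, seg: int, x_term: np.ndarray,
                     params: ModelParameters) -> VascularTree:
    """Trial tree: split ``seg`` at its midpoint and attach a terminal at
    ``x_term``.  The input tree is untouched; the trial is rescaled."""
    if tree.fixed_segment_mask[seg]:
        raise ValueError("cannot split a segment of the fixed root subtree")
    u = tree.parent[seg]
    x_bif = 0.5 * (tree.pos[u] + tree.pos[seg])
    trial = tree.split_and_attach(seg, x_bif, np.asarray(x_term, float))
    return rescale_tree(trial, params, inplace=True)


def optimize_bifurcation(tree: VascularTree, b: int, params: ModelParameters,
                         maxfev: int = 60) -> VascularTree:
    """Move bifurcation ``b`` to (locally) minimize total tree volume.

    The position is searched inside the triangle spanned by the three
    neighbour nodes (parent and both children), parametrized in barycentric
    coordinates, with a derivative-free simplex method; radii are re-solved
    hydraulically at every trial position.  The tree is updated in place and
    returned; the returned volume never exceeds the entry volume.
    """
    ch = tree.children_of(b)
    if ch.size != 2 or tree.parent[b] < 0:
        raise ValueError("bifurcation node must have a parent and two children")
    corners = np.array([tree.pos[tree.parent[b]], tree.pos[ch[0]],
                        tree.pos[ch[1]]])
    # barycentric coordinates of the current position via least squares
    A = np.column_stack([corners[0] - corners[2], corners[1] - corners[2]])
    sol, *_ = np.linalg.lstsq(A, tree.pos[b] - corners[2], rcond=None)
    x0 = np.clip(sol, 0.0, 1.0)
    if x0.sum() > 1.0:
        x0 /= x0.sum()
    n = tree.n_nodes
    rstar, dpress, radius = np.zeros(n), np.zeros(n), np.zeros(n)
    eta = tree._cache.get("eta_si")
    c = 8.0 * (np.asarray(eta) if eta is not None
               else np.full(n, params.eta_si)) / np.pi
    a1, a2, _ = _kernels.optimize_bifurcation_nm(
        tree.parent, tree.order, tree.length, tree.flow, c, params.gamma,
        params.dp_si, tree.pos, b, int(ch[0]), int(ch[1]), corners,
        float(x0[0]), float(x0[1]), maxfev, rstar, dpress, radius)
    _kernels._bif_eval(tree.parent, tree.order, tree.length, tree.flow, c,
                       params.gamma, params.dp_si, tree.pos, b, int(ch[0]),
                       int(ch[1]), corners, a1, a2, np.inf, rstar, dpress,
                       radius)
    rescale_tree(tree, params, inplace=True)
    return tree


def grow_step(tree: VascularTree, domain: PerfusionDomain,
              params: ModelParameters, rng: np.random.Generator,
              max_resample: int = 20) -> VascularTree:
    """Add one terminal: sample, try the n_con nearest segments, commit the
    lowest-volume connection.  Deterministic given the tree and rng state."""
    thr = threshold_schedule(domain.volume, tree.n_leaves, params.sampling_constant)
    last_err: Exception | None = None
    for _ in range(max_resample):
        try:
            x_term = sample_terminal_point(domain, tree, thr, rng,
                                           floor=params.l_min_si)
        except GrowthError as err:
            last_err = err
            continue
        best_vol = np.inf
        best_seg = -1
        best_tree = None
        for seg in nearest_segments(tree, x_term, params.n_con):
            if tree.fixed_segment_mask[seg]:
                continue
            trial = connect_terminal(tree, seg, x_term, params)
            optimize_bifurcation(trial, tree.n_nodes, params)
            vol = tree_volume_si(trial)
            if vol < best_vol or (vol == best_vol and seg < best_seg):
                best_vol, best_seg, best_tree = vol, int(seg), trial
        if best_tree is not None:
            return best_tree
    raise GrowthError("no admissible connection found") from last_err


def grow(tree: VascularTree, domain: PerfusionDomain, params: ModelParameters,
         rng: np.random.Generator, stop: int,
         stop_on_radius_floor: bool = False,
         callback=None, trace: list | None = None) -> VascularTree:
    """Repeat ``grow_step`` until the tree has ``stop`` terminals (or, with
    ``stop_on_radius_floor``, until a terminal radius falls below r_min).

    ``callback(tree, n_leaves)`` runs after each committed terminal and may
    return a replacement tree (used for interleaved geometry optimization).
    ``trace`` collects one (n_terminals, volume_mm3) row per committed
    terminal, for growth-curve logging.
    """
    from .hydraulics import tree_volume

    if stop < tree.n_leaves:
        raise ValueError("stop is below the current number of terminals")
    while tree.n_leaves < stop:
        tree = grow_step(tree, domain, params, rng)
        if trace is not None:
            trace.append((tree.n_leaves, tree_volume(tree)))
        if callback is not None:
            replacement = callback(tree, tree.n_leaves)
            if replacement is not None:
                tree = replacement
        if stop_on_radius_floor:
            if tree.radius[tree.leaves].min() < params.r_min_si:
                break
    return tree
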