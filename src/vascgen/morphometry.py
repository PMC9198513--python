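"""Morphometric analysis: Strahler ordering, branching ratios and
per-generation summaries of a vascular tree.

Strahler ordering starts at the leaves (order 1); a parent segment takes the
maximum order of its children, incremented by one when two or more children
tie at that maximum.  A node with a single child (monopodial continuation)
keeps the child's order.  Generations count the other way round: the root
segment is generation 1, and generation = root order - own order + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import units
from .tree import VascularTree


def strahler_orders(tree: VascularTree) -> np.ndarray:
    """Strahler order per node (the order of the node's incoming segment;
    the root node carries the order of the root segment)."""
    n = tree.n_nodes
    order_idx = tree.order
    ptr, idx = tree.children
    orders = np.zeros(n, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        v = order_idx[i]
        ch = idx[ptr[v]:ptr[v + 1]]
        if ch.size == 0:
            orders[v] = 1
        else:
            m = orders[ch].max()
            ties = int((orders[ch] == m).sum())
            orders[v] = m + 1 if (ch.size >= 2 and ties >= 2) else m
    return orders


def generations(tree: VascularTree) -> np.ndarray:
    """Generation index per node: root segment = generation 1."""
    orders = strahler_orders(tree)
    return orders[0] - orders + 1


def branching_ratio(tree: VascularTree, node: int) -> float:
    """Asymmetry measure delta_u = min child radius / max child radius."""
    ch = tree.children_of(node)
    if ch.size == 0:
        raise ValueError("branching ratio is undefined at a leaf")
    r = tree.radius[ch]
    return float(r.min() / r.max())


def branching_ratios(tree: VascularTree) -> np.ndarray:
    """delta_u for every node (NaN at leaves)."""
    n = tree.n_nodes
    out = np.full(n, np.nan)
    ptr, idx = tree.children
    for u in range(n):
        ch = idx[ptr[u]:ptr[u + 1]]
        if ch.size:
            r = tree.radius[ch]
            out[u] = r.min() / r.max()
    return out


@dataclass
class GenerationStats:
    """Per-generation aggregate of a Strahler-ordered tree."""

    generation: int
    segment_count: int
    mean_radius_mm: float
    mean_branching_ratio: float
    trifurcation_count: int
    monopodial_count: int
    low_delta_count: int  # bifurcations with delta < 0.25 (trunk-with-twig)


def generation_statistics(tree: VascularTree) -> list[GenerationStats]:
    """Aggregate segment counts, mean radii and branching asymmetry per
    generation.  Branching ratios are averaged over internal nodes whose
    incoming segment belongs to the generation; trifurcations are nodes of
    out-degree three, monopodial nodes have out-degree one."""
    gen = generations(tree)
    deltas = branching_ratios(tree)
    outdeg = tree.out_degree
    stats: list[GenerationStats] = []
    for g in range(1, int(gen[1:].max(initial=1)) + 1):
        seg_mask = np.zeros(tree.n_nodes, dtype=bool)
        seg_mask[1:] = gen[1:] == g
        node_mask = seg_mask.copy()
        node_mask[0] = gen[0] == g  # the root node belongs to generation 1
        if not seg_mask.any() and not node_mask.any():
            continue
        internal = node_mask & (outdeg > 0)
        d = deltas[internal]
        stats.append(GenerationStats(
            generation=g,
            segment_count=int(seg_mask.sum()),
            mean_radius_mm=float(np.mean(tree.radius[seg_mask]) / units.MM_TO_M)
            if seg_mask.any() else float("nan"),
            mean_branching_ratio=float(np.mean(d)) if d.size else float("nan"),
            trifurcation_count=int((outdeg[node_mask] == 3).sum()),
            monopodial_count=int((outdeg[node_mask] == 1).sum()),
            low_delta_count=int((d[~np.isnan(d)] < 0.25).sum()) if d.size else 0,
        ))
    return stats


def generation_table(tree: VascularTree) -> pd.DataFrame:
    """Generation statistics as a tidy DataFrame (one row per generation)."""
    return pd.DataFrame([s.__dict__ for s in generation_statistics(tree)])


def count_trifurcations(tree: VascularTree) -> int:
    return int((tree.out_degree == 3).sum())


def count_monopodial(tree: VascularTree) -> int:
    """Internal nodes with a single child (pass-through continuations)."""
    return int((tree.out_degree == 1).sum()) - 1 if tree.out_degree[0] == 1 \
        else int((tree.out_degree == 1).sum())


def compare_generation_stats(tree: VascularTree,
                             reference: pd.DataFrame) -> pd.DataFrame:
    """Align per-generation statistics of ``tree`` with a reference table.

    The reference needs columns ``generation``, ``segment_count``,
    ``mean_radius_mm`` and ``mean_branching_ratio`` (e.g. cast-derived
    morphometry).  Rows are matched on generation; non-overlapping
    generations are dropped with a warning.  Returns deltas (tree minus
    reference) and ratios per aligned generation.
    """
    import warnings

    own = generation_table(tree)
    merged = own.merge(reference, on="generation", suffixes=("", "_ref"))
    if len(merged) < max(len(own), len(reference)):
        warnings.warn("generation ranges differ; comparing the overlap only")
    out = pd.DataFrame({"generation": merged["generation"]})
    for col in ("segment_count", "mean_radius_mm", "mean_branching_ratio"):
        out[f"{col}_delta"] = merged[col] - merged[f"{col}_ref"]
        out[f"{col}_ratio"] = merged[col] / merged[f"{col}_ref"]
    return out
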