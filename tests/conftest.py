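"""Shared fixtures: parameter sets, hand-built trees and random-tree factories."""

from __future__ import annotations

import numpy as np
import pytest

import vascgen as vg
from vascgen import units
from vascgen.tree import VascularTree

MM = units.MM_TO_M


@pytest.fixture(scope="session")
def bench():
    """Benchmark box domain and parameters (terminal count left small)."""
    domain, params = vg.benchmark_fixture(n_term=50, n_con=8)
    return domain, params


@pytest.fixture(scope="session")
def params(bench):
    return bench[1]


def make_y_tree(params, spread=8.0, depth_mm=10.0, asym=0.0):
    """Root -> bifurcation -> two leaves, rescaled."""
    pos = np.array([
        [0.0, 0.0, 0.0],
        [depth_mm, 0.0, 0.0],
        [2 * depth_mm, spread, 0.0],
        [2 * depth_mm, -(spread - asym), 0.0],
    ]) * MM
    t = VascularTree(pos, np.array([-1, 0, 1, 1]))
    return vg.rescale_tree(t, params)


@pytest.fixture()
def y_tree(params):
    return make_y_tree(params)


def make_balanced_tree(depth: int, params, l_mm=10.0):
    """Perfect binary tree: every segment at depth d has the same length.

    Built so sibling branches fan out symmetrically (positions are only
    needed for lengths; the hydraulics depend on lengths alone).
    """
    parent = [-1]
    pos = [np.zeros(3)]
    frontier = [0]
    rng = np.random.default_rng(0)
    for d in range(depth):
        nxt = []
        for u in frontier:
            if d == 0 and u == 0:
                k = len(parent)
                parent.append(0)
                pos.append(pos[0] + np.array([l_mm, 0, 0.0]) * MM)
                nxt.append(k)
                continue
            for sgn in (+1.0, -1.0):
                k = len(parent)
                parent.append(u)
                direction = np.array([1.0, sgn * 1.0 / (d + 1), 0.1 * sgn])
                direction *= l_mm * MM / np.linalg.norm(direction)
                pos.append(pos[u] + direction)
                nxt.append(k)
        frontier = nxt
    t = VascularTree(np.array(pos), np.array(parent))
    return vg.rescale_tree(t, params)


@pytest.fixture()
def balanced3(params):
    return make_balanced_tree(3, params)


def make_random_tree(rng: np.random.Generator, n_leaves: int, params,
                     box_mm=60.0):
    """Random binary topology (sequential leaf insertion into random
    segments) with random node positions; rescaled."""
    pos = rng.uniform(0, box_mm, size=(2, 3)) * MM
    t = VascularTree(pos, np.array([-1, 0]))
    for _ in range(n_leaves - 1):
        seg = int(rng.integers(1, t.n_nodes))
        x = rng.uniform(0, box_mm, size=3) * MM
        mid = 0.5 * (t.pos[seg] + t.pos[t.parent[seg]])
        t = t.split_and_attach(seg, mid + rng.normal(0, 1e-4, 3), x)
    return vg.rescale_tree(t, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220087)
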