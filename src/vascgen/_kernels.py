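"""Low-level array kernels for the tree recursion and its adjoint.

The tree is stored as a parent array with node 0 as root; the segment into
node ``v`` is indexed by ``v`` (slot 0 unused).  All kernels take a BFS
topological ``order`` so that a single reversed sweep visits children before
parents.

``rescale`` implements the classic two-pass computation that makes a tree
hydraulically consistent for fixed topology, positions and flows: an upward
sweep accumulates reduced resistances ``Rstar`` (pressure drop from the
proximal end of a segment down to the leaves equals ``Rstar * Q / r^4``),
and a downward sweep fixes absolute radii from the prescribed total pressure
drop ``dp`` and node pressures ``D`` (pressure above terminal pressure).
With the radius power law r_parent^gamma = sum r_child^gamma the upward
recursion closes as

    Rstar_v = c_v * l_v + S_v^(4/gamma) / Q_v,
    S_v     = sum_children (Rstar_child * Q_child)^(gamma/4),

where ``c_v = 8 eta_v / pi``.  ``gradient_lengths`` is the hand-coded
reverse sweep (adjoint) of this computation, returning d(volume)/d(length)
per segment; the chain rule to node positions is applied by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_L_FLOOR = 1.0e-12  # m; guards the recursion against zero-length segments


def children_csr(parent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CSR adjacency (ptr, idx) of children lists, ordered by node id."""
    n = parent.shape[0]
    counts = np.bincount(parent[1:], minlength=n)
    ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    idx = np.argsort(parent[1:], kind="stable") + 1
    return ptr, idx.astype(np.int64)


@njit(cache=True)
def bfs_order(parent, ptr, idx):
    n = parent.shape[0]
    order = np.empty(n, dtype=np.int64)
    order[0] = 0
    head, tail = 0, 1
    while head < tail:
        u = order[head]
        head += 1
        for j in range(ptr[u], ptr[u + 1]):
            order[tail] = idx[j]
            tail += 1
    return order[:tail]


@njit(cache=True)
def subtree_leaf_counts(parent, order, out_degree):
    n = parent.shape[0]
    nl = np.zeros(n, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        v = order[i]
        if out_degree[v] == 0:
            nl[v] = 1
        if v != 0:
            nl[parent[v]] += nl[v]
    return nl


@njit(cache=True)
def rescale(parent, order, length, flow, c, gamma, dp, rstar, dpress, radius):
    """Two-pass hydraulic rescale; fills rstar, dpress (node) and radius."""
    n = parent.shape[0]
    s = np.zeros(n)
    e = 4.0 / gamma
    ei = gamma / 4.0
    for i in range(n - 1, -1, -1):
        v = order[i]
        if v == 0:
            continue
        l = length[v]
        if l < _L_FLOOR:
            l = _L_FLOOR
        if s[v] == 0.0:  # leaf segment
            rstar[v] = c[v] * l
        else:
            rstar[v] = c[v] * l + s[v] ** e / flow[v]
        s[parent[v]] += (rstar[v] * flow[v]) ** ei
    dpress[0] = dp
    for i in range(n):
        v = order[i]
        if v == 0:
            continue
        u = parent[v]
        radius[v] = (rstar[v] * flow[v] / dpress[u]) ** 0.25
        l = length[v]
        if l < _L_FLOOR:
            l = _L_FLOOR
        dpress[v] = dpress[u] * (rstar[v] - c[v] * l) / rstar[v]


@njit(cache=True)
def volume(length, radius):
    """Total tree volume sum_a pi * l_a * r_a^2 (slot 0 ignored)."""
    total = 0.0
    for v in range(1, length.shape[0]):
        total += length[v] * radius[v] * radius[v]
    return np.pi * total


@njit(cache=True)
def gradient_lengths(parent, order, length, flow, c, gamma, rstar, dpress, radius):
    """Adjoint sweep: d(volume)/d(length) per segment, given a rescale state."""
    n = parent.shape[0]
    s = np.zeros(n)
    ei = gamma / 4.0
    for i in range(n - 1, -1, -1):
        v = order[i]
        if v != 0:
            s[parent[v]] += (rstar[v] * flow[v]) ** ei
    dbar = np.zeros(n)
    # children before parents: when v is reached its own dbar is complete
    for i in range(n - 1, -1, -1):
        v = order[i]
        if v == 0:
            continue
        u = parent[v]
        l = length[v]
        if l < _L_FLOOR:
            l = _L_FLOOR
        fv = l * radius[v] * radius[v]  # segment volume / pi
        dbar[u] += -fv / (2.0 * dpress[u]) + dbar[v] * (rstar[v] - c[v] * l) / rstar[v]
    rbar = np.zeros(n)
    lbar = np.zeros(n)
    ex = (4.0 - gamma) / gamma
    for i in range(n):
        v = order[i]
        if v == 0:
            continue
        u = parent[v]
        l = length[v]
        if l < _L_FLOOR:
            l = _L_FLOOR
        fv = l * radius[v] * radius[v]
        rb = fv / (2.0 * rstar[v]) + dbar[v] * dpress[u] * c[v] * l / (rstar[v] * rstar[v])
        if u != 0:
            rb += rbar[u] * s[u] ** ex * (rstar[v] * flow[v]) ** (ei - 1.0) * flow[v] / flow[u]
        rbar[v] = rb
        lbar[v] = radius[v] * radius[v] + rbar[v] * c[v] - dbar[v] * dpress[u] * c[v] / rstar[v]
    return np.pi * lbar


@njit(cache=True)
def scatter_position_gradient(parent, pos, length, lbar, grad):
    """Chain rule l_v = |x_u - x_v| onto node positions; grad is (n, 3)."""
    n = parent.shape[0]
    for v in range(1, n):
        u = parent[v]
        l = length[v]
        if l < _L_FLOOR:
            l = _L_FLOOR
        for k in range(3):
            d = (pos[u, k] - pos[v, k]) / l * lbar[v]
            grad[u, k] += d
            grad[v, k] -= d


@njit(cache=True)
def euler_intervals(parent, ptr, idx):
    """DFS entry/exit times; w is in the subtree of v iff tin[v] <= tin[w] < tout[v]."""
    n = parent.shape[0]
    tin = np.empty(n, dtype=np.int64)
    tout = np.empty(n, dtype=np.int64)
    stack = np.empty(2 * n, dtype=np.int64)
    state = np.empty(2 * n, dtype=np.int64)
    top = 0
    stack[top] = 0
    state[top] = 0
    clock = 0
    while top >= 0:
        u = stack[top]
        if state[top] == 0:
            tin[u] = clock
            clock += 1
            state[top] = 1
            for j in range(ptr[u + 1] - 1, ptr[u] - 1, -1):
                top += 1
                stack[top] = idx[j]
                state[top] = 0
        else:
            tout[u] = clock
            top -= 1
    return tin, tout


@njit(cache=True)
def _bif_eval(parent, order, length, flow, c, gamma, dp, pos, b, ch1, ch2,
              corners, a1, a2, penalty, rstar, dpress, radius):
    a3 = 1.0 - a1 - a2
    if a1 < -1e-12 or a2 < -1e-12 or a3 < -1e-12:
        return penalty * (1.0 + a1 * a1 + a2 * a2 + a3 * a3)
    for k in range(3):
        pos[b, k] = a1 * corners[0, k] + a2 * corners[1, k] + a3 * corners[2, k]
    for v in (b, ch1, ch2):
        w = parent[v]
        s = 0.0
        for k in range(3):
            d = pos[w, k] - pos[v, k]
            s += d * d
        length[v] = s ** 0.5
    rescale(parent, order, length, flow, c, gamma, dp, rstar, dpress, radius)
    return volume(length, radius)


@njit(cache=True)
def optimize_bifurcation_nm(parent, order, length, flow, c, gamma, dp, pos,
                            b, ch1, ch2, corners, a1, a2, maxfev,
                            rstar, dpress, radius):
    """Nelder-Mead over the two barycentric dof of one bifurcation position.

    Returns (best_a1, best_a2, best_volume); the tree arrays are left at the
    best point found (caller re-evaluates to restore state)."""
    entry = _bif_eval(parent, order, length, flow, c, gamma, dp, pos, b, ch1,
                      ch2, corners, a1, a2, 1e30, rstar, dpress, radius)
    pen = 10.0 * entry
    best_a1, best_a2, best_v = a1, a2, entry
    # initial simplex around the (nudged-interior) start point
    s1 = min(max(a1, 0.05), 0.85)
    s2 = min(max(a2, 0.05), 0.85)
    if s1 + s2 > 0.9:
        f = 0.9 / (s1 + s2)
        s1 *= f
        s2 *= f
    vx = np.empty((3, 2))
    vf = np.empty(3)
    vx[0, 0], vx[0, 1] = s1, s2
    vx[1, 0], vx[1, 1] = s1 + 0.08, s2
    vx[2, 0], vx[2, 1] = s1, s2 + 0.08
    nfev = 0
    for i in range(3):
        vf[i] = _bif_eval(parent, order, length, flow, c, gamma, dp, pos, b,
                          ch1, ch2, corners, vx[i, 0], vx[i, 1], pen,
                          rstar, dpress, radius)
        nfev += 1
        if vf[i] < best_v:
            best_a1, best_a2, best_v = vx[i, 0], vx[i, 1], vf[i]
    while nfev < maxfev:
        # sort the three vertices
        for i in range(2):
            for j in range(i + 1, 3):
                if vf[j] < vf[i]:
                    vf[i], vf[j] = vf[j], vf[i]
                    for k in range(2):
                        vx[i, k], vx[j, k] = vx[j, k], vx[i, k]
        if abs(vf[2] - vf[0]) <= 1e-9 * (abs(vf[0]) + 1e-30) and \
           abs(vx[2, 0] - vx[0, 0]) + abs(vx[2, 1] - vx[0, 1]) < 1e-5:
            break
        c0 = 0.5 * (vx[0, 0] + vx[1, 0])
        c1 = 0.5 * (vx[0, 1] + vx[1, 1])
        xr0 = c0 + (c0 - vx[2, 0])
        xr1 = c1 + (c1 - vx[2, 1])
        fr = _bif_eval(parent, order, length, flow, c, gamma, dp, pos, b, ch1,
                       ch2, corners, xr0, xr1, pen, rstar, dpress, radius)
        nfev += 1
        if fr < best_v:
            best_a1, best_a2, best_v = xr0, xr1, fr
        if fr < vf[0]:
            xe0 = c0 + 2.0 * (c0 - vx[2, 0])
            xe1 = c1 + 2.0 * (c1 - vx[2, 1])
            fe = _bif_eval(parent, order, length, flow, c, gamma, dp, pos, b,
                           ch1, ch2, corners, xe0, xe1, pen, rstar, dpress,
                           radius)
            nfev += 1
            if fe < best_v:
                best_a1, best_a2, best_v = xe0, xe1, fe
            if fe < fr:
                vx[2, 0], vx[2, 1], vf[2] = xe0, xe1, fe
            else:
                vx[2, 0], vx[2, 1], vf[2] = xr0, xr1, fr
        elif fr < vf[1]:
            vx[2, 0], vx[2, 1], vf[2] = xr0, xr1, fr
        else:
            xc0 = c0 + 0.5 * (vx[2, 0] - c0)
            xc1 = c1 + 0.5 * (vx[2, 1] - c1)
            fc = _bif_eval(parent, order, length, flow, c, gamma, dp, pos, b,
                           ch1, ch2, corners, xc0, xc1, pen, rstar, dpress,
                           radius)
            nfev += 1
            if fc < best_v:
                best_a1, best_a2, best_v = xc0, xc1, fc
            if fc < vf[2]:
                vx[2, 0], vx[2, 1], vf[2] = xc0, xc1, fc
            else:  # shrink towards the best vertex
                for i in range(1, 3):
                    vx[i, 0] = vx[0, 0] + 0.5 * (vx[i, 0] - vx[0, 0])
                    vx[i, 1] = vx[0, 1] + 0.5 * (vx[i, 1] - vx[0, 1])
                    vf[i] = _bif_eval(parent, order, length, flow, c, gamma,
                                      dp, pos, b, ch1, ch2, corners,
                                      vx[i, 0], vx[i, 1], pen, rstar, dpress,
                                      radius)
                    nfev += 1
                    if vf[i] < best_v:
                        best_a1, best_a2, best_v = vx[i, 0], vx[i, 1], vf[i]
    return best_a1, best_a2, best_v


def point_segment_distances(x: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distances from point ``x`` (3,) to closed segments p0[i]-p1[i] (m, 3)."""
    d = p1 - p0
    w = x[None, :] - p0
    dd = np.einsum("ij,ij->i", d, d)
    t = np.einsum("ij,ij->i", w, d) / np.where(dd > 0.0, dd, 1.0)
    t = np.clip(t, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(x[None, :] - proj, axis=1)
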