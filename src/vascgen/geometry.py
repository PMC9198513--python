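"""Global geometry optimization of a vascular tree as a nonlinear program.

For a fixed topology and fixed flows, the tree volume

    min  sum_a l_a r_a^2            (the constant pi is dropped)

is minimized over the stacked variable vector y = (x, p, l, r) subject to

    x_u = xbar_u                    for u in V_k and all leaves,
    l_a = lbar_a,  r_a = rbar_a     for a in A_k (frozen root subtree),
    l_uv^2 = |x_u - x_v|^2          length consistency (squared form),
    r_uv^gamma = sum_w r_vw^gamma   radius power law at free internal nodes,
    p_u - p_v = (8 eta / pi) Q_uv l_uv / r_uv^4   Poiseuille drop per arc,
    p_u = 0 at leaves,  p_0 = dp    boundary pressures (p_term = 0 inside),

with box bounds l in [l-, l+], r in [r-, r+].  The variable dimension is
4|V| + 2|A| = 6|V| - 2.

Two solvers are provided.  The default ("reduced") eliminates p, l and r
exactly: lengths follow from positions and the pressure/power-law equations
determine all radii through the classic two-pass recursion, so the equality
constraints hold to machine precision by construction and the objective is
minimized over the free node positions only, using the hand-coded adjoint
gradient of the recursion with L-BFGS-B.  The full-space formulation (used
for cross-checks on small trees) solves the program as stated with SLSQP on
a scaled variable vector (positions/lengths in cm, radii in mm, pressures in
units of dp) to keep the r^4 terms well conditioned.

After optimization, non-terminal segments shorter than their diameter are
degenerate and are pruned, re-parenting their children one level up; this is
the mechanism that creates trifurcations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _kernels, units
from .hydraulics import rescale_tree, tree_volume
from .parameters import ModelParameters
from .tree import VascularTree

_SX = 100.0     # m -> cm for positions and lengths
_SR = 1000.0    # m -> mm for radii


@dataclass
class NLPProblem:
    """The geometry program for one tree: variables, bounds, residuals.

    Variable layout (scaled units): x (3|V|, cm), p (|V|, units of dp),
    l (|A|, cm), r (|A|, mm), with segment k stored at index k-1.
    """

    tree: VascularTree
    params: ModelParameters
    y0: np.ndarray = field(init=False)
    lb: np.ndarray = field(init=False)
    ub: np.ndarray = field(init=False)

    def __post_init__(self):
        t, p = self.tree, self.params
        n = t.n_nodes
        self.n_nodes = n
        self.n_segments = n - 1
        self.dim = 4 * n + 2 * (n - 1)
        self._ix = slice(0, 3 * n)
        self._ip = slice(3 * n, 4 * n)
        self._il = slice(4 * n, 5 * n - 1)
        self._ir = slice(5 * n - 1, 6 * n - 2)
        self.y0 = self.pack(t.pos, t.pressure, t.length[1:], t.radius[1:])
        self.lb = np.full(self.dim, -np.inf)
        self.ub = np.full(self.dim, np.inf)
        l_lo, l_hi = p.l_min_si, p.bound_multiplier * t.length[1:].max()
        r_lo, r_hi = p.r_min_si, p.bound_multiplier * t.radius[1:].max()
        self.lb[self._il], self.ub[self._il] = l_lo * _SX, l_hi * _SX
        self.lb[self._ir], self.ub[self._ir] = r_lo * _SR, r_hi * _SR
        # fix frozen/leaf positions and frozen segments through the bounds
        fixed_pos = t.fixed_node_mask | t.leaf_mask
        m = np.repeat(fixed_pos, 3)
        self.lb[self._ix][...] = np.where(m, self.y0[self._ix], -np.inf)
        self.ub[self._ix][...] = np.where(m, self.y0[self._ix], np.inf)
        fseg = t.fixed_segment_mask[1:]
        if fseg.any():
            for sl in (self._il, self._ir):
                lo, hi = self.lb[sl], self.ub[sl]
                lo[fseg] = self.y0[sl][fseg]
                hi[fseg] = self.y0[sl][fseg]
        bad = (self.y0 < self.lb) | (self.y0 > self.ub)
        if bad.any():
            warnings.warn("initial tree violates box bounds; widening bounds "
                          f"on {int(bad.sum())} variables")
            self.lb = np.minimum(self.lb, self.y0)
            self.ub = np.maximum(self.ub, self.y0)
        self.fixed_position_mask = fixed_pos

    # -- packing -----------------------------------------------------------
    def pack(self, pos, pressure, length, radius) -> np.ndarray:
        y = np.empty(self.dim)
        y[self._ix] = (pos * _SX).ravel()
        y[self._ip] = pressure / self.params.dp_si
        y[self._il] = length * _SX
        y[self._ir] = radius * _SR
        return y

    def unpack(self, y: np.ndarray):
        n = self.n_nodes
        pos = (y[self._ix] / _SX).reshape(n, 3)
        pressure = y[self._ip] * self.params.dp_si
        length = np.concatenate([[0.0], y[self._il] / _SX])
        radius = np.concatenate([[0.0], y[self._ir] / _SR])
        return pos, pressure, length, radius

    # -- objective ---------------------------------------------------------
    def objective(self, y: np.ndarray) -> float:
        """sum_a l_a r_a^2 in scaled units (cm mm^2)."""
        return float(np.sum(y[self._il] * y[self._ir] ** 2))

    def objective_grad(self, y: np.ndarray) -> np.ndarray:
        g = np.zeros(self.dim)
        l, r = y[self._il], y[self._ir]
        g[self._il] = r ** 2
        g[self._ir] = 2.0 * l * r
        return g

    # -- equality constraints ---------------------------------------------
    def constraints(self, y: np.ndarray) -> np.ndarray:
        """Residual vector of all equality constraints (scaled units)."""
        t, p = self.tree, self.params
        pos, pressure, length, radius = self.unpack(y)
        parent = t.parent
        res = []
        # position fixings (root subtree and leaves)
        fixed = np.flatnonzero(self.fixed_position_mask)
        res.append(((pos[fixed] - t.pos[fixed]) * _SX).ravel())
        # frozen lengths/radii on A_k
        fseg = np.flatnonzero(t.fixed_segment_mask)
        res.append((length[fseg] - t.length[fseg]) * _SX)
        res.append((radius[fseg] - t.radius[fseg]) * _SR)
        # squared length consistency off A_k
        free_mask = ~t.fixed_segment_mask
        free_mask[0] = False
        free_seg = np.flatnonzero(free_mask)
        d = pos[free_seg] - pos[parent[free_seg]]
        res.append((length[free_seg] ** 2 - np.einsum("ij,ij->i", d, d)) * _SX ** 2)
        # radius power law at free internal nodes
        gam = p.gamma
        ptr, idx = t.children
        for v in range(1, t.n_nodes):
            if t.out_degree[v] > 0 and not t.fixed_node_mask[v]:
                ch = idx[ptr[v]:ptr[v + 1]]
                res.append([(radius[v] * _SR) ** gam
                            - np.sum((radius[ch] * _SR) ** gam)])
        # Poiseuille pressure drop on every arc
        eta = t._cache.get("eta_si", np.full(t.n_nodes, p.eta_si))
        seg = np.arange(1, t.n_nodes)
        drop = (8.0 * np.asarray(eta)[seg] / np.pi) * t.flow[seg] \
            * length[seg] / np.maximum(radius[seg], 1e-12) ** 4
        res.append((pressure[parent[seg]] - pressure[seg] - drop) / p.dp_si)
        # boundary pressures
        res.append(pressure[t.leaves] / p.dp_si)
        res.append([pressure[0] / p.dp_si - 1.0])
        return np.concatenate([np.atleast_1d(np.asarray(r, float)) for r in res])

    def constraints_free(self, y: np.ndarray) -> np.ndarray:
        """The non-fixing equality constraints only (length consistency,
        power law, pressure drops, boundary pressures); the variable
        fixings are imposed through degenerate box bounds instead."""
        n_fix = 3 * int(self.fixed_position_mask.sum()) \
            + 2 * int(self.tree.fixed_segment_mask.sum())
        return self.constraints(y)[n_fix:]

    def max_scaled_residual(self, y: np.ndarray | None = None) -> float:
        y = self.y0 if y is None else y
        c = self.constraints(y)
        return float(np.max(np.abs(c))) if c.size else 0.0


@dataclass
class NLPSolution:
    objective: float          # sum l r^2 in scaled units
    volume_mm3: float         # pi sum l r^2, mm^3
    max_residual: float       # recomputed independently of the solver
    status: str
    iterations: int


def scaled_residuals(tree: VascularTree, params: ModelParameters) -> dict[str, float]:
    """Independent dimensionless feasibility residuals of a rescaled tree.

    Returns the maxima of: relative length/position mismatch, relative
    power-law residual per internal node, per-arc pressure-drop residual and
    leaf/root pressure residuals (both relative to the total drop dp).
    """
    t, p = tree, params
    seg = np.arange(1, t.n_nodes)
    d = np.linalg.norm(t.pos[seg] - t.pos[t.parent[seg]], axis=1)
    len_res = np.max(np.abs(t.length[seg] - d)
                     / np.maximum(t.length[seg], p.l_min_si)) if seg.size else 0.0
    ptr, idx = t.children
    murray = 0.0
    for v in range(t.n_nodes):
        ch = idx[ptr[v]:ptr[v + 1]]
        if ch.size and v != 0 and not t.fixed_node_mask[v]:
            rp = t.radius[v] ** p.gamma
            murray = max(murray, abs(rp - np.sum(t.radius[ch] ** p.gamma)) / rp)
    eta = t._cache.get("eta_si", np.full(t.n_nodes, p.eta_si))
    drop = (8.0 * np.asarray(eta)[seg] / np.pi) * t.flow[seg] * t.length[seg] \
        / np.maximum(t.radius[seg], 1e-12) ** 4
    press = np.max(np.abs(t.pressure[t.parent[seg]] - t.pressure[seg] - drop)
                   / p.dp_si) if seg.size else 0.0
    leaf = np.max(np.abs(t.pressure[t.leaves])) / p.dp_si
    root = abs(t.pressure[0] - p.dp_si) / p.dp_si
    return {"length": float(len_res), "murray": float(murray),
            "pressure_drop": float(press), "leaf_pressure": float(leaf),
            "root_pressure": float(root)}


def assemble_nlp(tree: VascularTree, params: ModelParameters) -> NLPProblem:
    """Build the geometry program for ``tree`` (flows must be current)."""
    t = rescale_tree(tree, params)
    return NLPProblem(t, params)


# ---------------------------------------------------------------------------
# reduced-space solver


def free_position_nodes(tree: VascularTree) -> np.ndarray:
    """Nodes whose positions are optimization variables: internal, not in
    the frozen root subtree, not leaves."""
    return np.flatnonzero(~tree.fixed_node_mask & ~tree.leaf_mask)


class _ReducedObjective:
    """Volume and adjoint gradient over free node positions (mm units).

    The box bound l >= l_min of the full program is enforced by a stiff
    quadratic penalty: without it, shrinking a terminal segment is always
    profitable (its volume scales like l^(3/2) at fixed pressure drop) and
    free bifurcations would collapse onto the fixed leaves.
    """

    #: penalty stiffness, mm^3 per mm^2 of bound violation
    LENGTH_PENALTY = 50.0

    def __init__(self, tree: VascularTree, params: ModelParameters,
                 free: np.ndarray):
        self.t = tree
        self.params = params
        self.free = free
        n = tree.n_nodes
        self._rstar = np.zeros(n)
        self._dpress = np.zeros(n)
        self._radius = np.zeros(n)
        self._grad = np.zeros((n, 3))
        eta = tree._cache.get("eta_si")
        self._c = 8.0 * (np.asarray(eta) if eta is not None
                         else np.full(n, params.eta_si)) / np.pi

    def __call__(self, z_mm: np.ndarray):
        t = self.t
        t.pos[self.free] = z_mm.reshape(-1, 3) * units.MM_TO_M
        diff = t.pos[1:] - t.pos[t.parent[1:]]
        t.length[1:] = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        _kernels.rescale(t.parent, t.order, t.length, t.flow, self._c,
                         self.params.gamma, self.params.dp_si,
                         self._rstar, self._dpress, self._radius)
        vol_mm3 = _kernels.volume(t.length, self._radius) / units.MM_TO_M ** 3
        lbar = _kernels.gradient_lengths(t.parent, t.order, t.length, t.flow,
                                         self._c, self.params.gamma,
                                         self._rstar, self._dpress, self._radius)
        viol_mm = np.maximum(self.params.l_min - t.length / units.MM_TO_M, 0.0)
        viol_mm[0] = 0.0
        if viol_mm.any():
            vol_mm3 += self.LENGTH_PENALTY * float(np.sum(viol_mm ** 2))
            # d(penalty)/d(l_m), folded into the same scatter as the volume
            lbar = lbar - 2.0 * self.LENGTH_PENALTY * viol_mm * 1e-6
        self._grad[:] = 0.0
        _kernels.scatter_position_gradient(t.parent, t.pos, t.length, lbar,
                                           self._grad)
        # d(m^3)/d(m) -> d(mm^3)/d(mm)
        g = self._grad[self.free].ravel() * 1e6
        return vol_mm3, g


def solve_geometry(tree: VascularTree, params: ModelParameters,
                   method: str = "reduced", maxiter: int = 400,
                   free_nodes: np.ndarray | None = None,
                   gtol: float = 1e-8) -> tuple[VascularTree, NLPSolution]:
    """Solve the geometry program starting from the (feasible) tree.

    Returns the optimized tree and a solution report whose residual is
    recomputed independently of the solver.  The returned objective never
    exceeds the initial one: the best iterate is kept.
    """
    t = rescale_tree(tree, params)
    if method == "full":
        return _solve_geometry_full(t, params, maxiter)
    free = free_position_nodes(t) if free_nodes is None else np.asarray(free_nodes)
    vol0 = tree_volume(t)
    if free.size == 0:
        res = scaled_residuals(t, params)
        return t, NLPSolution(vol0 / np.pi, vol0, max(res.values()), "fixed", 0)
    work = t.copy()
    obj = _ReducedObjective(work, params, free)
    z0 = (work.pos[free] / units.MM_TO_M).ravel()
    vol0_pen, _ = obj(z0.copy())
    best = {"z": z0.copy(), "vol": vol0_pen}

    def fun(z):
        vol, g = obj(z)
        if vol < best["vol"]:
            best["z"], best["vol"] = z.copy(), vol
        return vol, g

    out = minimize(fun, z0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12})
    t.pos[free] = best["z"].reshape(-1, 3) * units.MM_TO_M
    t._invalidate()
    t = rescale_tree(t, params, inplace=True)
    res = scaled_residuals(t, params)
    vol = tree_volume(t)
    status = "converged" if (out.success or vol <= vol0) else "not_converged"
    if vol > vol0:  # solver failure: keep the input tree
        t = rescale_tree(tree, params)
        vol = tree_volume(t)
        status = "kept_input"
    return t, NLPSolution(vol / np.pi, vol, max(res.values()), status,
                          int(out.nit))


def _solve_geometry_full(tree: VascularTree, params: ModelParameters,
                         maxiter: int) -> tuple[VascularTree, NLPSolution]:
    """Full-space SLSQP solve of the program as stated (small trees)."""
    prob = NLPProblem(tree, params)
    cons = {"type": "eq", "fun": prob.constraints_free}
    bounds = list(zip(prob.lb, prob.ub))
    out = minimize(prob.objective, prob.y0, jac=prob.objective_grad,
                   method="SLSQP", bounds=bounds, constraints=[cons],
                   options={"maxiter": maxiter, "ftol": 1e-12})
    y = out.x if out.fun <= prob.objective(prob.y0) else prob.y0
    pos, pressure, length, radius = prob.unpack(y)
    t = tree.copy()
    t.pos = pos
    t._invalidate()
    t.length = length
    t.radius = radius
    t.pressure = pressure
    t.flow = tree.flow.copy()
    resid = prob.max_scaled_residual(y)
    return t, NLPSolution(prob.objective(y), tree_volume(t), resid,
                          "converged" if out.success else str(out.message),
                          int(out.nit))


def optimize_geometry(tree: VascularTree, params: ModelParameters,
                      rounds: int = 3, **kw) -> VascularTree:
    """Alternate global geometry solves with degenerate-segment pruning
    until the volume stops improving (pruning changes the topology, so a
    re-solve can find a better geometry for the merged branchings)."""
    t, _ = solve_geometry(tree, params, **kw)
    t = prune_degenerate(t, params)
    vol = tree_volume(t)
    for _ in range(rounds - 1):
        t2, _ = solve_geometry(t, params, **kw)
        t2 = prune_degenerate(t2, params)
        vol2 = tree_volume(t2)
        if vol2 >= vol * (1.0 - 1e-6):
            if vol2 < vol:
                t = t2
            break
        t, vol = t2, vol2
    return t


# ---------------------------------------------------------------------------
# degenerate-segment pruning


def prune_degenerate(tree: VascularTree, params: ModelParameters) -> VascularTree:
    """Remove non-terminal segments shorter than their diameter (l < 2r),
    re-parenting children one level up; iterates to a fixpoint.  This is
    what creates trifurcations (and higher branchings).  Terminal segments
    and the root segment are never pruned."""
    t = rescale_tree(tree, params)
    while True:
        seg = np.arange(1, t.n_nodes)
        degen = (t.out_degree[seg] > 0) & (t.length[seg] < 2.0 * t.radius[seg])
        cand = seg[degen]
        cand = cand[t.parent[cand] != 0]  # protect the root segment
        if cand.size == 0:
            if degen.any():
                warnings.warn("degenerate root segment left in place")
            return t
        t = rescale_tree(t.remove_node(int(cand[0])), params, inplace=True)
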