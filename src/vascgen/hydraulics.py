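"""Hydraulic closed forms: viscosity, resistance, radius power law, flows,
volume, and the two-pass rescale that makes a tree hydraulically consistent.

The model treats segments as rigid straight tubes carrying steady laminar
Poiseuille flow of an incompressible Newtonian fluid.  Terminal outflow is
homogeneous (every leaf delivers the same flow into the microcirculation)
and every leaf sits at the same terminal pressure, so the tree realises the
prescribed total pressure drop along every root-to-leaf path.
"""

from __future__ import annotations

import numpy as np

from . import _kernels, units
from .parameters import ModelParameters
from .tree import VascularTree

#: radius (mm) at which the Fahraeus-Lindqvist denominator degenerates
_FL_R_SINGULAR_MM = 0.00055


def effective_viscosity(r_mm: float | np.ndarray, params: ModelParameters) -> float | np.ndarray:
    """Dynamic blood viscosity in cP for a vessel of radius ``r_mm`` (mm).

    With ``use_fl_viscosity`` off this is the constant bulk viscosity.
    Otherwise the empirical Fahraeus-Lindqvist fit is evaluated:

        eta(r) = 1.125 (kappa + kappa^2 [6 e^(-170 r) - 2.44 e^(-8.09 r^0.64) + 2.2]),
        kappa  = r^2 / (r - 0.00055)^2,   r in mm,

    which decreases towards small radii (cell-depleted plasma layer at the
    wall) and tends to the bulk value 3.6 cP for large vessels.
    """
    r = np.asarray(r_mm, dtype=float)
    if np.any(r <= _FL_R_SINGULAR_MM):
        raise ValueError(f"radius must exceed {_FL_R_SINGULAR_MM} mm")
    if not params.use_fl_viscosity:
        out = np.full_like(r, params.eta)
        return float(out) if out.ndim == 0 else out
    kappa = r ** 2 / (r - _FL_R_SINGULAR_MM) ** 2
    bracket = 6.0 * np.exp(-170.0 * r) - 2.44 * np.exp(-8.09 * r ** 0.64) + 2.2
    eta = 1.125 * (kappa + kappa ** 2 * bracket)
    return float(eta) if eta.ndim == 0 else eta


def poiseuille_resistance(length, radius, eta):
    """Hydrodynamic resistance R = 8 eta l / (pi r^4) of a straight tube.

    Unit-agnostic: any consistent unit system (e.g. SI) works.  Homogeneous
    of degree +1 in length and -4 in radius.
    """
    length = np.asarray(length, dtype=float)
    radius = np.asarray(radius, dtype=float)
    if np.any(radius <= 0):
        raise ValueError("radius must be positive")
    if np.any(length < 0):
        raise ValueError("length must be non-negative")
    if np.any(np.asarray(eta) <= 0):
        raise ValueError("viscosity must be positive")
    out = 8.0 * eta * length / (np.pi * radius ** 4)
    return float(out) if out.ndim == 0 else out


def murray_parent_radius(daughter_radii, gamma: float) -> float:
    """Parent radius from the power law r_p^gamma = sum r_d^gamma."""
    r = np.asarray(daughter_radii, dtype=float)
    if r.size == 0:
        raise ValueError("at least one daughter radius required")
    if np.any(r <= 0) or gamma <= 0:
        raise ValueError("radii and gamma must be positive")
    return float(np.sum(r ** gamma) ** (1.0 / gamma))


def distribute_flows(tree: VascularTree, params: ModelParameters) -> VascularTree:
    """Set segment flows: Q_perf/|L| at each leaf, summed upward (Kirchhoff).

    Flows are exact multiples of Q_perf/|L|, so conservation at internal
    nodes holds without round-off beyond a single division.
    """
    nl = _kernels.subtree_leaf_counts(tree.parent, tree.order, tree.out_degree)
    tree.flow = nl * (params.q_perf_si / tree.n_leaves)
    tree.flow[0] = 0.0
    return tree


def tree_volume(tree: VascularTree) -> float:
    """Total intravascular volume sum_a pi l_a r_a^2, in mm^3."""
    return _kernels.volume(tree.length, tree.radius) / units.MM_TO_M ** 3


def tree_volume_si(tree: VascularTree) -> float:
    return _kernels.volume(tree.length, tree.radius)


def rescale_tree(tree: VascularTree, params: ModelParameters,
                 inplace: bool = False) -> VascularTree:
    """Recompute radii and pressures for the current topology and positions.

    Upward pass accumulates reduced resistances and radius ratios from the
    power law; downward pass fixes absolute radii from the root radius that
    realises the total pressure drop, and node pressures from the per-segment
    Poiseuille drops.  After the call every leaf sits exactly at terminal
    pressure and the power law holds at every free internal node.

    With Fahraeus-Lindqvist viscosity enabled the radius-dependent viscosity
    is resolved by fixed-point iteration (viscosity frozen per sweep).
    """
    if params.dp <= 0:
        raise ValueError("total pressure drop must be positive")
    t = tree if inplace else tree.copy()
    t.sync_lengths()
    distribute_flows(t, params)
    n = t.n_nodes
    if n < 2:
        return t
    rstar = np.zeros(n)
    dpress = np.zeros(n)
    radius = np.zeros(n)
    eta = np.full(n, params.eta_si)
    for _ in range(60):
        c = 8.0 * eta / np.pi
        _kernels.rescale(t.parent, t.order, t.length, t.flow, c,
                         params.gamma, params.dp_si, rstar, dpress, radius)
        if not params.use_fl_viscosity:
            break
        eta_new = segment_viscosities_si_from_radius(radius, params)
        if np.max(np.abs(eta_new - eta)) <= 1e-12 * params.eta_si:
            eta = eta_new
            break
        eta = eta_new
    t.radius = radius
    t.pressure = dpress
    t._cache["rstar"] = rstar
    t._cache["eta_si"] = eta
    return t


def segment_viscosities_si_from_radius(radius_m: np.ndarray,
                                       params: ModelParameters) -> np.ndarray:
    r_mm = np.maximum(radius_m / units.MM_TO_M, 2.0 * _FL_R_SINGULAR_MM)
    eta_cp = np.asarray(effective_viscosity(r_mm, params), dtype=float)
    return eta_cp * units.CP_TO_PAS


def rescaled_volume(tree: VascularTree, params: ModelParameters) -> float:
    """Volume (mm^3) of the tree after a hydraulic rescale (tree untouched)."""
    return tree_volume(rescale_tree(tree, params))
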