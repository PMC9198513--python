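"""Perfusion domains: the spatial region to be supplied by the tree.

A domain provides a deterministic containment test, its volume and a
uniform sampler.  Shipped shapes are an axis-aligned box (the shallow-slab
benchmark geometry), analytic ellipsoids and constructive unions/differences
of them (used for the synthetic organ-like fixture), plus an optional
triangulated-surface domain backed by trimesh.

Terminal points are drawn by rejection sampling from the bounding box and
must keep a minimum distance to all existing segments; the threshold decays
with the cube root of the volume per terminal (mean inter-point spacing) and
is relaxed geometrically when the sampler starves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels, units
from .tree import VascularTree


class GrowthError(RuntimeError):
    """Raised when no admissible terminal point can be found."""


class PerfusionDomain:
    """Abstract perfusion region Omega in R^3 (all coordinates in m)."""

    def contains(self, x: np.ndarray) -> np.ndarray | bool:
        """True iff x lies in the closed region; accepts (3,) or (n, 3)."""
        raise NotImplementedError

    @property
    def volume(self) -> float:
        """Region volume in m^3."""
        raise NotImplementedError

    @property
    def volume_cm3(self) -> float:
        return self.volume / units.CM3_TO_M3

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lo, hi) in m."""
        raise NotImplementedError

    def sample_uniform(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Uniform draws inside the region via bounding-box rejection."""
        lo, hi = self.bounds
        out = np.empty((size, 3))
        filled = 0
        while filled < size:
            m = max(2 * (size - filled), 64)
            cand = rng.uniform(lo, hi, size=(m, 3))
            inside = np.asarray(self.contains(cand), dtype=bool)
            take = cand[inside][:size - filled]
            out[filled:filled + take.shape[0]] = take
            filled += take.shape[0]
        return out


@dataclass
class BoxDomain(PerfusionDomain):
    """Axis-aligned box [lo, hi] (m)."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if np.any(self.hi <= self.lo):
            raise ValueError("degenerate box: hi must exceed lo on every axis")

    def contains(self, x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        inside = np.all((x >= self.lo) & (x <= self.hi), axis=1)
        return bool(inside[0]) if single else inside

    @property
    def volume(self) -> float:
        return float(np.prod(self.hi - self.lo))

    @property
    def bounds(self):
        return self.lo, self.hi


@dataclass
class Ellipsoid:
    center: np.ndarray
    semiaxes: np.ndarray

    def inside(self, x: np.ndarray) -> np.ndarray:
        d = (x - self.center) / self.semiaxes
        return np.einsum("ij,ij->i", d, d) <= 1.0


class EllipsoidUnionDomain(PerfusionDomain):
    """Union of ellipsoids minus a union of spherical "bites".

    Smooth non-convex organ-like region; the volume is estimated once by
    Monte Carlo over the bounding box with a fixed internal seed, so the
    domain itself stays deterministic.
    """

    def __init__(self, ellipsoids: list[Ellipsoid],
                 bites: list[tuple[np.ndarray, float]] = (),
                 mc_samples: int = 400_000):
        if not ellipsoids:
            raise ValueError("at least one ellipsoid required")
        self.ellipsoids = [Ellipsoid(np.asarray(e.center, float),
                                     np.asarray(e.semiaxes, float))
                           for e in ellipsoids]
        self.bites = [(np.asarray(c, float), float(r)) for c, r in bites]
        los = np.array([e.center - e.semiaxes for e in self.ellipsoids])
        his = np.array([e.center + e.semiaxes for e in self.ellipsoids])
        self._lo, self._hi = los.min(axis=0), his.max(axis=0)
        rng = np.random.default_rng(20220087)
        pts = rng.uniform(self._lo, self._hi, size=(mc_samples, 3))
        frac = np.mean(self.contains(pts))
        self._volume = float(np.prod(self._hi - self._lo) * frac)

    def contains(self, x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        inside = np.zeros(x.shape[0], dtype=bool)
        for e in self.ellipsoids:
            inside |= e.inside(x)
        for c, r in self.bites:
            inside &= np.linalg.norm(x - c, axis=1) > r
        return bool(inside[0]) if single else inside

    @property
    def volume(self) -> float:
        return self._volume

    @property
    def bounds(self):
        return self._lo, self._hi


class MeshDomain(PerfusionDomain):
    """Closed triangulated surface, containment via trimesh (winding number /
    ray parity).  Boundary points count as inside up to mesh tolerance."""

    def __init__(self, mesh):
        import trimesh  # optional dependency

        if not isinstance(mesh, trimesh.Trimesh):
            mesh = trimesh.load(mesh, force="mesh")
        if not mesh.is_watertight:
            raise ValueError("surface mesh must be watertight")
        self.mesh = mesh

    @classmethod
    def from_file(cls, path) -> "MeshDomain":
        return cls(path)

    def contains(self, x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        inside = self._ray_parity(np.atleast_2d(x))
        return bool(inside[0]) if single else inside

    def _ray_parity(self, pts: np.ndarray) -> np.ndarray:
        """Crossing-parity containment (Moller-Trumbore against all
        triangles; an irrational ray direction avoids edge grazing)."""
        tri = self.mesh.triangles  # (m, 3, 3)
        d = np.array([0.57735027, 0.62321371, 0.52783234])
        d /= np.linalg.norm(d)
        v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
        e1, e2 = v1 - v0, v2 - v0
        h = np.cross(d, e2)                     # (m, 3)
        a = np.einsum("mj,mj->m", e1, h)        # (m,)
        ok = np.abs(a) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        out = np.empty(pts.shape[0], dtype=bool)
        for i, p in enumerate(pts):
            s = p[None, :] - v0
            u = np.einsum("mj,mj->m", s, h) * inv
            q = np.cross(s, e1)
            v = q @ d * inv
            t = np.einsum("mj,mj->m", e2, q) * inv
            hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
            out[i] = bool(hit.sum() % 2)
        return out

    @property
    def volume(self) -> float:
        return float(self.mesh.volume)

    @property
    def bounds(self):
        b = self.mesh.bounds
        return np.asarray(b[0], float), np.asarray(b[1], float)


# ---------------------------------------------------------------------------
# distances and terminal sampling


def point_segment_distance(x, p0, p1) -> float:
    """Distance from a point to the closed segment p0-p1 (orthogonal
    projection clamped to the segment; degenerate segments allowed)."""
    x = np.asarray(x, float)
    d = _kernels.point_segment_distances(
        x, np.atleast_2d(np.asarray(p0, float)), np.atleast_2d(np.asarray(p1, float)))
    return float(d[0])


def distances_to_tree(x: np.ndarray, tree: VascularTree) -> np.ndarray:
    """Distances (m) from x to every segment, indexed by distal node - 1."""
    p1 = tree.pos[1:]
    p0 = tree.pos[tree.parent[1:]]
    return _kernels.point_segment_distances(np.asarray(x, float), p0, p1)


def threshold_schedule(v_perf_m3: float, n_current: int, c: float = 0.5) -> float:
    """Minimum sampling distance d(n) = c (V/max(n,1))^(1/3) in m.

    Cube-root-of-volume-per-terminal law: the mean spacing of n uniform
    points in volume V.  Strictly decreasing in n.
    """
    if n_current < 0:
        raise ValueError("n_current must be non-negative")
    return c * (v_perf_m3 / max(n_current, 1)) ** (1.0 / 3.0)


def sample_terminal_point(domain: PerfusionDomain, tree: VascularTree | None,
                          threshold: float, rng: np.random.Generator,
                          floor: float = 0.0,
                          batch: int = 64, max_batches_per_level: int = 16,
                          relax: float = 0.9) -> np.ndarray:
    """Draw a uniform point of Omega at distance > threshold from all
    segments.  After ``batch * max_batches_per_level`` rejections the
    threshold is relaxed by ``relax``; below ``floor`` sampling fails."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    thr = threshold
    while True:
        for _ in range(max_batches_per_level):
            pts = domain.sample_uniform(rng, batch)
            if tree is None or tree.n_nodes < 2 or thr == 0.0:
                return pts[0]
            for x in pts:
                if distances_to_tree(x, tree).min() > thr:
                    return x
        if thr <= floor:
            raise GrowthError("terminal sampling exhausted below the distance floor")
        thr = max(thr * relax, 0.0)
        if thr < floor:
            thr = floor
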