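"""End-to-end generation framework and the shipped problem fixtures.

The combined pipeline grows the tree with CCO to an intermediate size,
runs one global geometry optimization, searches the topology by simulated
annealing, then continues CCO growth with periodic global geometry
optimization (period from the n_geo schedule) and finishes with a full
geometry solve plus degenerate-segment pruning.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from . import units
from .domain import BoxDomain, Ellipsoid, EllipsoidUnionDomain, PerfusionDomain
from .geometry import optimize_geometry
from .growth import grow
from .hydraulics import rescale_tree, tree_volume
from .parameters import ModelParameters
from .topology import optimize_topology
from .tree import VascularTree


def benchmark_fixture(n_term: int = 6000, n_con: int = 32,
                      **overrides) -> tuple[PerfusionDomain, ModelParameters]:
    """The shallow-slab benchmark: a 9 x 7 x 1.6 cm box perfused from one
    corner with 500 ml/min across a 100 -> 60 mm Hg drop, gamma = 2.55."""
    domain = BoxDomain(np.zeros(3),
                       np.array([9.0, 7.0, 1.6]) * units.CM_TO_M)
    params = ModelParameters(q_perf=500.0, p_perf=100.0, p_term=60.0,
                             eta=3.6, gamma=2.55, n_term=n_term, n_con=n_con,
                             **overrides)
    return domain, params


def benchmark_root_position() -> np.ndarray:
    """Root entry point of the benchmark: a corner of the box."""
    return np.zeros(3)


def liver_like_fixture(n_term: int = 6000, n_con: int = 30,
                       **overrides) -> tuple[PerfusionDomain, ModelParameters]:
    """A synthetic organ-like stand-in for a portal-vein perfusion volume.

    Smooth non-convex region (two overlapping ellipsoids with a spherical
    bite removed) of approximately 1500 cm^3, perfused with 1000 ml/min
    across a 12 -> 8 mm Hg drop with classical Murray exponent 3.0.  The
    shape is synthetic; only volume and parameters are physiological.
    """
    s = 0.975 * units.CM_TO_M  # overall scale chosen for ~1500 cm^3
    domain = EllipsoidUnionDomain(
        ellipsoids=[
            Ellipsoid(np.array([0.0, 0.0, 0.0]) * s,
                      np.array([10.5, 6.5, 5.0]) * s),
            Ellipsoid(np.array([7.0, 2.0, 1.0]) * s,
                      np.array([6.5, 5.0, 4.5]) * s),
        ],
        bites=[(np.array([3.0, -5.5, 0.0]) * s, 3.2 * s)],
    )
    params = ModelParameters(q_perf=1000.0, p_perf=12.0, p_term=8.0,
                             eta=3.6, gamma=3.0, n_term=n_term, n_con=n_con,
                             **overrides)
    return domain, params


def liver_like_root_position() -> np.ndarray:
    return np.array([-9.0, 0.0, 0.0]) * units.CM_TO_M


@dataclass
class StageReport:
    name: str
    seconds: float
    volume_mm3: float
    n_leaves: int


@dataclass
class RunReport:
    seed: int
    stages: list[StageReport] = field(default_factory=list)
    volume_cco_only: float | None = None

    def record(self, name, t0, tree):
        self.stages.append(StageReport(name, time.perf_counter() - t0,
                                       tree_volume(tree), tree.n_leaves))

    @property
    def final_volume(self) -> float:
        return self.stages[-1].volume_mm3

    def to_dict(self) -> dict:
        return {"seed": self.seed,
                "stages": [s.__dict__ for s in self.stages]}

    def __str__(self) -> str:
        lines = [f"run (seed {self.seed})"]
        for s in self.stages:
            lines.append(f"  {s.name:<22} {s.seconds:8.1f} s  "
                         f"volume {s.volume_mm3:10.2f} mm^3  "
                         f"terminals {s.n_leaves}")
        return "\n".join(lines)


def grow_cco_only(domain: PerfusionDomain, params: ModelParameters,
                  seed: int, n_term: int | None = None,
                  root_pos: np.ndarray | None = None,
                  trace: list | None = None) -> VascularTree:
    """Plain CCO growth to n_term terminals (no global optimization)."""
    n_term = params.n_term if n_term is None else n_term
    rng = np.random.default_rng(seed)
    root = benchmark_root_position() if root_pos is None else root_pos
    first = domain.sample_uniform(rng, 1)[0]
    tree = VascularTree.from_root_segment(root, first)
    tree = rescale_tree(tree, params, inplace=True)
    return grow(tree, domain, params, rng, stop=n_term, trace=trace)


class FrameworkError(RuntimeError):
    """A pipeline stage failed; ``partial_tree`` holds the tree grown so
    far (export it for diagnosis)."""

    def __init__(self, stage: str, cause: Exception,
                 partial_tree: VascularTree | None):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.partial_tree = partial_tree


def run_framework(domain: PerfusionDomain, params: ModelParameters,
                  seed: int | None = None,
                  root_pos: np.ndarray | None = None,
                  report: RunReport | None = None) -> tuple[VascularTree, RunReport]:
    """The full generation pipeline (growth + geometry + topology).

    Stages: CCO growth to min(n_intermediate, n_term) -> global geometry
    optimization -> simulated-annealing topology optimization -> continued
    CCO growth with a geometry solve + pruning every n_geo added terminals
    -> final full geometry solve and pruning.  A stage failure raises
    :class:`FrameworkError` carrying the partial tree.
    """
    seed = params.seed if seed is None else seed
    report = report or RunReport(seed=seed)
    rng = np.random.default_rng(seed)
    root = benchmark_root_position() if root_pos is None else root_pos
    holder: dict = {"tree": None}
    try:
        return _run_framework(domain, params, rng, root, report, holder)
    except Exception as err:  # attach the partial tree for diagnosis
        stage = report.stages[-1].name if report.stages else "initialization"
        raise FrameworkError(stage, err, holder["tree"]) from err


def _run_framework(domain, params, rng, root, report, holder):
    t0 = time.perf_counter()
    first = domain.sample_uniform(rng, 1)[0]
    tree = VascularTree.from_root_segment(root, first)
    tree = rescale_tree(tree, params, inplace=True)
    holder["tree"] = tree
    intermediate = min(params.n_intermediate, params.n_term)

    def keep(t):
        holder["tree"] = t
        return t

    tree = keep(grow(tree, domain, params, rng, stop=intermediate,
                     callback=lambda t, n: keep(t) and None))
    report.record("cco_growth_initial", t0, tree)

    t0 = time.perf_counter()
    tree = keep(optimize_geometry(tree, params))
    report.record("geometry_initial", t0, tree)

    t0 = time.perf_counter()
    tree = keep(optimize_topology(tree, params, rng))
    report.record("topology_sa", t0, tree)

    if params.n_term > intermediate:
        t0 = time.perf_counter()
        state = {"since_geo": 0}

        def periodic_geometry(t, n_leaves):
            holder["tree"] = t
            state["since_geo"] += 1
            if state["since_geo"] >= params.n_geo(t.n_nodes):
                state["since_geo"] = 0
                return optimize_geometry(t, params, rounds=2)
            return None

        tree = keep(grow(tree, domain, params, rng, stop=params.n_term,
                         callback=periodic_geometry))
        report.record("cco_growth_continued", t0, tree)

    t0 = time.perf_counter()
    tree = keep(optimize_geometry(tree, params))
    report.record("geometry_final", t0, tree)
    return tree, report


def save_report(report: RunReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
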