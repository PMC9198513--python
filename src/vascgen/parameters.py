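"""Model and algorithm parameters for synthetic vascular tree generation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import units


@dataclass
class SAParameters:
    """Simulated-annealing schedule for the topology search.

    ``t0`` is the initial temperature in the units of the (scaled) tree
    volume objective; ``None`` means calibrate it from probe moves so that a
    move of median cost is accepted with probability one half.  Cooling is
    geometric with factor ``cooling`` per iteration.
    """

    t0: float | None = None
    cooling: float = 0.995
    iterations: int = 2000
    max_consecutive_rejections: int = 500
    full_solve_every: int = 50  # accepted moves between full geometry solves
    local_radius: int = 3       # graph distance freed around a swap
    reheat_after: int | None = None  # stagnant iterations before a reheat
                                     # (None: iterations // 8, at least 50)
    reheat_level: float = 1.0        # first reheat, as a fraction of t0;
                                     # each further reheat halves the level


def default_n_geo_schedule(n_nodes: int) -> int:
    """Period (in added terminals) between global geometry optimizations.

    Optimize every 20 added terminals while the tree is small, then double
    the period each time the node count doubles, capped at 500 for very
    dense trees.
    """
    period = 20
    threshold = 1000
    while n_nodes > threshold and period < 500:
        period = min(2 * period, 500)
        threshold *= 2
    return period


@dataclass
class ModelParameters:
    """Physiological and algorithmic constants of the tree model.

    Values are given in conventional physiological units and converted to SI
    internally (``*_si`` properties).

    Parameters
    ----------
    q_perf : float
        Total perfusion flow at the root, ml/min.
    p_perf, p_term : float
        Perfusion (root) and terminal pressure, mm Hg.
    eta : float
        Dynamic blood viscosity, cP.  Used as a constant unless
        ``use_fl_viscosity`` is set, in which case the radius-dependent
        Fahraeus-Lindqvist viscosity is substituted per segment.
    gamma : float
        Branching exponent of the radius power law (3.0 = classical Murray).
    n_term : int
        Target number of terminal segments.
    n_con : int
        Number of nearest segments tested when connecting a new terminal.
    r_min, l_min : float
        Physical lower bounds on segment radius and length, mm.
    bound_multiplier : float
        Factor on the initial maxima giving the artificial upper bounds of
        the geometry program.
    """

    q_perf: float = 500.0
    p_perf: float = 100.0
    p_term: float = 60.0
    eta: float = 3.6
    use_fl_viscosity: bool = False
    gamma: float = 2.55
    n_term: int = 6000
    n_con: int = 32
    r_min: float = 0.1
    l_min: float = 0.2
    bound_multiplier: float = 2.0
    n_intermediate: int = 500   # tree size at which topology optimization runs
    sa_params: SAParameters = field(default_factory=SAParameters)
    seed: int = 0
    sampling_constant: float = 0.5  # c in the terminal-distance threshold law

    def __post_init__(self) -> None:
        if self.q_perf <= 0:
            raise ValueError("q_perf must be positive")
        if self.p_perf <= self.p_term:
            raise ValueError("p_perf must exceed p_term")
        if not (2.0 <= self.gamma <= 3.0):
            raise ValueError("gamma must lie in [2.0, 3.0]")
        if self.r_min <= 0 or self.l_min <= 0:
            raise ValueError("r_min and l_min must be positive")
        if self.n_con < 1:
            raise ValueError("n_con must be at least 1")

    # -- derived quantities (SI) -------------------------------------------
    @property
    def dp(self) -> float:
        """Total pressure drop root -> terminals, mm Hg."""
        return self.p_perf - self.p_term

    @property
    def dp_si(self) -> float:
        return units.mmhg_to_pa(self.dp)

    @property
    def q_perf_si(self) -> float:
        return units.mlmin_to_m3s(self.q_perf)

    @property
    def eta_si(self) -> float:
        return units.cp_to_pas(self.eta)

    @property
    def r_min_si(self) -> float:
        return units.mm_to_m(self.r_min)

    @property
    def l_min_si(self) -> float:
        return units.mm_to_m(self.l_min)

    def n_geo(self, n_nodes: int) -> int:
        return default_n_geo_schedule(n_nodes)

    def with_(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)
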