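# Methods

`vascgen` generates synthetic arterial (or venous) trees that supply a
prescribed perfusion volume, by combining incremental constructive growth
with rigorous global optimization of the tree geometry and a stochastic
search over tree topologies.  This note records the model, the numerical
choices, and the limits of what the test suite demonstrates.

## Model

A tree T = (V, A) consists of nodes u with positions x_u and segments
a = uv, each a rigid straight cylinder of radius r_a and length
l_a = ||x_u − x_v||.  Blood is treated as an incompressible Newtonian fluid
in steady laminar flow, so each segment obeys Poiseuille's law with
hydrodynamic resistance

    R_a = 8 η l_a / (π r_a⁴),

and the pressure drop across a segment is Δp_a = R_a Q_a.  The tree is
perfused with total flow Q_perf at the root; every terminal (leaf) delivers
the same flow Q_perf/|L| into the microcirculation at the same terminal
pressure p_term (p_term is set to zero internally and re-added for
reporting).  Flows are therefore fixed by the topology alone (Kirchhoff
sums of the equal leaf outflows).  At every branching the radii satisfy the
power law

    r_parent^γ = Σ r_child^γ,

with branching exponent γ ∈ [2, 3] (γ = 3 is classical Murray).  The tree
is assumed to minimize the metabolic cost of maintaining blood volume,

    f_T = Σ_a π l_a r_a².

The Fåhræus–Lindqvist radius dependence of viscosity is available behind a
flag (`use_fl_viscosity`); by default viscosity is the constant bulk value
η = 3.6 cP, which is also what the shipped benchmark uses.  When enabled,
the per-segment viscosity η(r_a) is resolved by fixed-point iteration of
the radius recursion (viscosity frozen per sweep; convergence to 1e-12
relative in a handful of sweeps).  It deliberately enters only the
hydraulic rescale and reporting, not the geometry program: the program's
constraint Jacobian would otherwise need dη/dr terms whose effect is far
below the optimizer's tolerance at the radii of interest.

### Hydraulic rescale

For fixed topology, positions and flows, pressures and radii are determined
by requiring all leaves at p_term and the root at p_perf.  This is computed
by the classic two-pass recursion: an upward sweep accumulates reduced
resistances

    R*_a = (8 η_a / π) l_a + S_v^{4/γ} / Q_a,
    S_v = Σ_children (R*_b Q_b)^{γ/4},

(leaf segments: R*_a = (8η/π) l_a), and a downward sweep fixes
r_a⁴ = R*_a Q_a / D_u from the pressure head D_u at the proximal node
(D_root = Δp).  The recursion enforces the radius power law and equal leaf
pressures *exactly* (to round-off), which is why all feasibility residuals
in the test suite sit at ~1e-15.

## Geometry optimization

The global geometry program minimizes Σ l_a r_a² (π dropped as a constant)
over y = (x, p, l, r) subject to: frozen positions for the root subtree
T_k and all leaves; length consistency l² = ||x_u − x_v||² (squared form,
smooth at coincident nodes); the radius power law at free internal nodes;
per-segment Poiseuille pressure drops; leaf and root boundary pressures;
and box bounds l ≥ 0.2 mm (validity of Poiseuille flow), r ≥ 0.1 mm (the
pre-arteriolar cut-off), with upper bounds at twice the initial maxima.
The variable dimension is 4|V| + 2|A| = 6|V| − 2.

Two solvers are provided:

- **Reduced space (default).**  All equality constraints are eliminated
  exactly: lengths follow from positions and the two-pass recursion yields
  radii and pressures, so the only free variables are the positions of the
  unfrozen internal nodes.  The objective gradient with respect to those
  positions is computed by a hand-coded adjoint (reverse sweep) of the
  recursion in O(|A|), verified against finite differences, and the
  minimization uses L-BFGS-B.  The l ≥ l⁻ bound is enforced by a stiff
  quadratic penalty (50 mm³ per mm² of violation): without it, shrinking a
  terminal segment is always profitable because its volume scales like
  l^{3/2} at fixed pressure drop, and free bifurcations would collapse onto
  the fixed leaves.  At the penalty equilibrium lengths settle within a few
  microns of the bound.  The r ≥ r⁻ bound is not active at the shipped
  problem sizes (terminal radii stay well above 0.1 mm below ~10⁴
  terminals) and is left to the full-space formulation.
- **Full space.**  The program exactly as stated, solved with SLSQP on a
  scaled variable vector (positions and lengths in cm, radii in mm,
  pressures in units of Δp — the r⁴ terms span six orders of magnitude
  otherwise).  Practical for small trees; the test suite uses it as an
  independent cross-check of the reduced solver on Y-trees (agreement to
  ~1e-12 in volume).

Feasibility is always re-verified by an independent residual evaluator
(dimensionless forms: relative length mismatch, relative power-law residual,
pressure residuals over Δp), never by the solver's own report.

After a solve, any non-terminal segment shorter than its diameter
(l < 2r, strict) is degenerate: it is removed and its children re-parented
one level up, possibly creating a trifurcation (or higher branching when
degenerate segments chain).  Pruning iterates to a fixpoint; terminal
segments and the root segment are never pruned.  `optimize_geometry`
alternates solving and pruning (pruning changes the topology, so a re-solve
can improve the merged branchings further); it converges in 2–3 rounds.

## Constructive growth (CCO)

Growth adds one terminal at a time: a candidate point is drawn uniformly in
the perfusion domain, rejected if closer than a threshold to any existing
segment; the threshold follows the mean-spacing law d(n) = c (V/n)^{1/3}
(c = 0.5) and is relaxed by ×0.9 whenever a batch of draws starves, with a
floor at l_min.  The point is then tentatively connected to each of the
N_con nearest segments by splitting the segment at its midpoint; each trial
bifurcation position is optimized inside the triangle of its three
neighbours (barycentric parametrization, derivative-free Nelder–Mead,
radii re-solved hydraulically at every trial point), and the connection
with the smallest total volume is committed (ties broken by segment
creation index).  Growth is bit-reproducible for a fixed seed.

## Topology optimization

The number of binary topologies grows as the Catalan numbers, so the
discrete search uses simulated annealing over subtree-swap moves of two
kinds: (a) a segment (with its whole subtree) is re-attached under a
different existing internal node, which can raise that node's out-degree;
(b) the segment's parent bifurcation is spliced out of its current
position and re-inserted to split another segment's interior — the classic
exchange of a proximal point from one parent segment to another, which
preserves the node count and binary structure.  Moves are discarded if
they would create a cycle, would leave the old parent childless, touch the
frozen root subtree, or start with a new segment at least twice the
current length (such moves almost never improve).  Each trial is geometry-optimized cheaply (only nodes within
graph distance 3 of the swap are freed), with a full solve every 50
accepted moves and a final full solve with pruning on the best tree; the
volume change is accepted by the Metropolis rule p = exp(−Δf/T).

The initial temperature is calibrated so that a probe move of median |Δf|
is accepted with probability one half; cooling is geometric (0.995 per
iteration).  When the best volume stagnates for iterations/8 steps the
chain restarts from the best tree at a reheated temperature that halves on
every further reheat (basin hopping); on a 5-leaf instance with an
exhaustively enumerable topology space this lifts the exact-optimum hit
rate from ~6/10 to ≥9/10 seeded runs without affecting larger runs.  The
search stops at the iteration budget or after 500 consecutive rejections.

## Combined pipeline

`run_framework` grows to an intermediate size (default 500 terminals),
geometry-optimizes, runs the topology search, continues growth with a
global geometry solve + pruning every N_geo added terminals (N_geo = 20 up
to 1000 nodes, doubling as the node count doubles, capped at 500), and
finishes with a full geometry solve and pruning.

## Synthetic problem fixtures

- **Benchmark box**: 9 × 7 × 1.6 cm slab, root at a corner, Q_perf =
  500 ml/min, p_perf/p_term = 100/60 mm Hg, η = 3.6 cP, γ = 2.55.  This is
  the standard configuration for exercising the growth and optimization
  machinery; no external data is needed.
- **Organ-like domain**: a smooth non-convex region (union of two
  overlapping ellipsoids with a spherical bite removed) scaled to
  ≈1500 cm³, with portal-vein-like parameters Q_perf = 1000 ml/min,
  p_perf/p_term = 12/8 mm Hg, γ = 3.0.  The *shape* is synthetic — it
  stands in for a segmented organ surface and makes no anatomical claim;
  only its volume and the pressure/flow parameters are physiological.
  Containment is analytic; the volume is a fixed-seed Monte-Carlo estimate,
  so the domain is deterministic.

What the fixtures do *not* emulate: real organ boundary geometry, spatially
heterogeneous terminal densities, the competing venous/arterial trees of a
real organ, and curved or tapered vessels.  Tests passing on these fixtures
therefore demonstrate the correctness and the qualitative optimization
behaviour of the algorithms, not anatomical fidelity of any particular
organ.

## Problem sizes used by the test suite and the acceptance script

Large reference runs for this class of generator use thousands to tens of
thousands of terminals.  The package's own verification uses reduced sizes,
chosen once: the geometry-effect measurements run at N_term = 1000 (script)
and 600 (test suite) over 3 seeds; the combined framework measurements at
N_term = 500 (script, annealing budget 2000) and 300 (tests, budget 1500);
seed-convergence at N_term = 200 over 5 seeds with an annealing
budget of 6000 — the across-seed convergence of final volumes is an
asymptotic property of the annealing search and only emerges at larger
budgets.  At these sizes
a single global geometry solve reduces CCO tree volume by ≈2–3.5% (the
effect grows with tree size), and the topology stage adds ≈1–3% more.

## Numerical choices and degenerate inputs

- Internal computation is SI (m, Pa, Pa·s, m³/s); the API and all file
  formats use mm, mm Hg, cP, ml/min.  Conversions happen once, at the
  boundary.
- Zero-length segments are clamped to 1e-12 m inside the recursion so the
  rescale stays finite during line searches; the length penalty keeps
  converged solutions away from the clamp.
- Murray aggregation at a node with a single child reduces to r_child =
  r_parent (series resistance), so monopodial nodes need no special case.
- Strahler ordering with non-binary nodes: a parent takes the maximum child
  order, incremented only when ≥2 children tie at that maximum; an
  out-degree-1 node passes its child's order through.  Generations count
  down from the root segment (generation 1).
- "Monopodial branch" counts are reported two ways, as the ambiguity is
  real: nodes of out-degree 1, and bifurcations with branching ratio
  δ < 0.25 (trunk-with-twig patterns); both appear in the per-generation
  statistics table.
- Equal-volume connection candidates are resolved by the lowest segment
  creation index; degeneracy triggers use strict l < 2r (ties keep the
  segment).
- Solver failure policy: if a geometry solve cannot improve the (feasible)
  warm start, the previous tree is kept and growth continues.

## Known limitations

- The reduced geometry solver is a local optimizer; different warm starts
  can reach different local minima (the full-space interior-point view has
  the same property).  Volume reductions quoted above are for the local
  optimum reached from the CCO warm start.
- Frozen root subtrees (k > 0) freeze positions in both solvers, but the
  frozen-segment radius equations are honoured only by the full-space
  formulation; the reduced solver re-derives all radii from the power law.
- Segments are not tested for leaving a non-convex domain; only terminal
  points are constrained to lie inside.
- No collision/intersection tests between non-adjacent segments.
- Pulsatile flow, vessel-wall mechanics, generation-dependent γ and
  coupled multi-tree generation are out of scope.
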