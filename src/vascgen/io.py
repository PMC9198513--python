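"""Tree import/export: VTK legacy polydata, POV-Ray scene text, CSV stats.

The VTK export writes one two-point polyline per segment with positions in
mm, segment radius and Strahler generation as cell data and node pressure
(mm Hg) as point data.  The format is the plain-text legacy VTK polydata
dialect, readable by ParaView and re-importable here for round-trips.
"""

from __future__ import annotations

import numpy as np

from . import units
from .morphometry import generation_table, generations
from .parameters import ModelParameters
from .tree import VascularTree


def export_vtk(tree: VascularTree, path, params: ModelParameters | None = None) -> None:
    n = tree.n_nodes
    pos_mm = tree.pos / units.MM_TO_M
    gen = generations(tree)
    p_term = params.p_term if params is not None else 0.0
    pressure = tree.pressures_mmhg(p_term)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("synthetic vascular tree (positions mm, pressure mmHg)\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for x in pos_mm:
            fh.write(f"{x[0]:.12g} {x[1]:.12g} {x[2]:.12g}\n")
        m = tree.n_segments
        fh.write(f"LINES {m} {3 * m}\n")
        for v in range(1, n):
            fh.write(f"2 {tree.parent[v]} {v}\n")
        fh.write(f"CELL_DATA {m}\n")
        fh.write("SCALARS radius_mm double 1\nLOOKUP_TABLE default\n")
        for v in range(1, n):
            fh.write(f"{tree.radius[v] / units.MM_TO_M:.12g}\n")
        fh.write("SCALARS generation int 1\nLOOKUP_TABLE default\n")
        for v in range(1, n):
            fh.write(f"{gen[v]}\n")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS pressure_mmhg double 1\nLOOKUP_TABLE default\n")
        for v in range(n):
            fh.write(f"{pressure[v]:.12g}\n")


def import_vtk(path) -> VascularTree:
    """Re-import a tree written by :func:`export_vtk`."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0

    def seek(prefix):
        nonlocal i
        while not tokens[i].startswith(prefix):
            i += 1
        return tokens[i]

    header = seek("POINTS").split()
    n = int(header[1])
    pts = np.array([[float(v) for v in tokens[i + 1 + k].split()]
                    for k in range(n)]) * units.MM_TO_M
    header = seek("LINES").split()
    m = int(header[1])
    parent = np.full(n, -1, dtype=np.int64)
    for k in range(m):
        _, a, b = tokens[i + 1 + k].split()
        parent[int(b)] = int(a)
    tree = VascularTree(pts, parent)
    seek("SCALARS radius_mm")
    i += 2
    for v in range(1, n):
        tree.radius[v] = float(tokens[i + v - 1]) * units.MM_TO_M
    return tree


def export_pov(tree: VascularTree, path) -> None:
    """POV-Ray scene text: a sphere per node, a cylinder per segment
    (the rendering convention: branching points as spheres, segments as
    cylinders).  Coordinates in mm."""
    pos = tree.pos / units.MM_TO_M
    r_mm = tree.radius / units.MM_TO_M
    node_r = np.zeros(tree.n_nodes)
    node_r[1:] = r_mm[1:]
    ptr, idx = tree.children
    for u in range(tree.n_nodes):
        ch = idx[ptr[u]:ptr[u + 1]]
        if ch.size:
            node_r[u] = max(node_r[u], r_mm[ch].max())
    with open(path, "w") as fh:
        fh.write("// synthetic vascular tree (mm)\n")
        for u in range(tree.n_nodes):
            x = pos[u]
            fh.write(f"sphere {{ <{x[0]:.6g},{x[1]:.6g},{x[2]:.6g}>, "
                     f"{node_r[u]:.6g} }}\n")
        for v in range(1, tree.n_nodes):
            a, b = pos[tree.parent[v]], pos[v]
            fh.write(f"cylinder {{ <{a[0]:.6g},{a[1]:.6g},{a[2]:.6g}>, "
                     f"<{b[0]:.6g},{b[1]:.6g},{b[2]:.6g}>, {r_mm[v]:.6g} }}\n")


def export_stats_csv(tree: VascularTree, path) -> None:
    """Per-generation morphometry table as CSV."""
    generation_table(tree).to_csv(path, index=False)


def export_tree(tree: VascularTree, path, fmt: str = "vtk",
                params: ModelParameters | None = None) -> None:
    if fmt in ("vtk", "vtp"):
        export_vtk(tree, path, params)
    elif fmt == "pov":
        export_pov(tree, path)
    elif fmt == "csv":
        export_stats_csv(tree, path)
    else:
        raise ValueError(f"unknown export format: {fmt}")
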