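"""Array-backed rooted vascular tree.

Node 0 is the root (the proximal point of the feeding vessel).  Every other
node carries exactly one incoming segment, so segments are indexed by their
distal node id; slot 0 of the per-segment arrays is unused.  Node ids are
contiguous and follow creation order, which the growth algorithm uses as a
deterministic tie-break.

Internal units are SI (positions in m, radii/lengths in m, flows in m^3/s,
pressures stored as Pa above terminal pressure).
"""

from __future__ import annotations

import numpy as np

from . import _kernels, units


class VascularTree:
    """Rooted branching network with per-node position/pressure and
    per-segment radius/length/flow.

    Out-degree > 2 (trifurcations and beyond) is supported.  A fixed root
    subtree of depth ``fixed_depth`` (k) has frozen node positions; k = 0
    freezes only the root position.
    """

    def __init__(self, pos: np.ndarray, parent: np.ndarray, fixed_depth: int = 0):
        pos = np.asarray(pos, dtype=np.float64).reshape(-1, 3)
        parent = np.asarray(parent, dtype=np.int64)
        if parent.shape[0] != pos.shape[0]:
            raise ValueError("parent and pos must have matching length")
        if parent[0] != -1:
            raise ValueError("node 0 must be the root (parent -1)")
        if parent.shape[0] > 1 and not np.all((parent[1:] >= 0) & (parent[1:] < parent.shape[0])):
            raise ValueError("invalid parent indices")
        self.pos = pos
        self.parent = parent
        self.fixed_depth = int(fixed_depth)
        n = pos.shape[0]
        self.radius = np.zeros(n)
        self.length = np.zeros(n)
        self.flow = np.zeros(n)
        self.pressure = np.zeros(n)  # Pa above p_term, per node
        self._cache: dict = {}
        self.sync_lengths()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_root_segment(cls, x_root, x_term, fixed_depth: int = 0) -> "VascularTree":
        """The smallest tree: one segment from the root to a first terminal."""
        return cls(np.array([x_root, x_term], dtype=float), np.array([-1, 0]), fixed_depth)

    def copy(self) -> "VascularTree":
        t = object.__new__(VascularTree)
        t.pos = self.pos.copy()
        t.parent = self.parent.copy()
        t.fixed_depth = self.fixed_depth
        t.radius = self.radius.copy()
        t.length = self.length.copy()
        t.flow = self.flow.copy()
        t.pressure = self.pressure.copy()
        t._cache = {}
        return t

    # -- cached topology views ---------------------------------------------
    def _invalidate(self) -> None:
        self._cache = {}

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def n_segments(self) -> int:
        return self.parent.shape[0] - 1

    @property
    def children(self) -> tuple[np.ndarray, np.ndarray]:
        if "children" not in self._cache:
            self._cache["children"] = _kernels.children_csr(self.parent)
        return self._cache["children"]

    def children_of(self, u: int) -> np.ndarray:
        ptr, idx = self.children
        return idx[ptr[u]:ptr[u + 1]]

    @property
    def order(self) -> np.ndarray:
        """BFS topological order (root first); also the connectivity check."""
        if "order" not in self._cache:
            ptr, idx = self.children
            order = _kernels.bfs_order(self.parent, ptr, idx)
            if order.shape[0] != self.n_nodes:
                raise ValueError("tree is not connected")
            self._cache["order"] = order
        return self._cache["order"]

    @property
    def out_degree(self) -> np.ndarray:
        if "out_degree" not in self._cache:
            self._cache["out_degree"] = np.bincount(self.parent[1:], minlength=self.n_nodes)
        return self._cache["out_degree"]

    @property
    def leaf_mask(self) -> np.ndarray:
        return self.out_degree == 0

    @property
    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.leaf_mask)

    @property
    def n_leaves(self) -> int:
        return int(self.leaf_mask.sum())

    @property
    def depth(self) -> np.ndarray:
        if "depth" not in self._cache:
            d = np.zeros(self.n_nodes, dtype=np.int64)
            for v in self.order[1:]:
                d[v] = d[self.parent[v]] + 1
            self._cache["depth"] = d
        return self._cache["depth"]

    @property
    def fixed_node_mask(self) -> np.ndarray:
        """Nodes of the frozen root subtree T_k (k = 0: only the root)."""
        return self.depth <= self.fixed_depth

    @property
    def fixed_segment_mask(self) -> np.ndarray:
        """Segments of A_k, i.e. whose distal node lies within depth k."""
        m = self.fixed_node_mask.copy()
        m[0] = False
        return m

    def euler_intervals(self) -> tuple[np.ndarray, np.ndarray]:
        if "euler" not in self._cache:
            ptr, idx = self.children
            self._cache["euler"] = _kernels.euler_intervals(self.parent, ptr, idx)
        return self._cache["euler"]

    # -- geometry ------------------------------------------------------------
    def sync_lengths(self) -> None:
        if self.n_nodes > 1:
            diff = self.pos[1:] - self.pos[self.parent[1:]]
            self.length[1:] = np.linalg.norm(diff, axis=1)
        self.length[0] = 0.0

    # -- structural edits (return new trees; node ids stay contiguous) ------
    def split_and_attach(self, seg: int, x_bif, x_term) -> "VascularTree":
        """Split segment ``seg`` at a new bifurcation node and hang a new
        terminal from it.  The bifurcation starts at ``x_bif`` and the
        terminal at ``x_term``; new nodes get the next ids (b = n, t = n+1)."""
        n = self.n_nodes
        pos = np.vstack([self.pos, np.asarray(x_bif, float), np.asarray(x_term, float)])
        parent = np.concatenate([self.parent, [self.parent[seg], n]])
        parent[seg] = n
        t = VascularTree(pos, parent, self.fixed_depth)
        return t

    def reattach(self, seg: int, new_parent: int) -> "VascularTree":
        """Move segment ``seg`` (with its whole subtree) under ``new_parent``."""
        parent = self.parent.copy()
        parent[seg] = new_parent
        t = VascularTree(self.pos.copy(), parent, self.fixed_depth)
        return t

    def splice_reattach(self, seg: int, target: int) -> "VascularTree":
        """Move the proximal point of ``seg`` onto another segment: the
        (binary) parent node of ``seg`` is spliced out of its current
        position and re-inserted to split the segment whose distal node is
        ``target``, keeping the node count and binary structure intact."""
        u = int(self.parent[seg])
        ch = self.children_of(u)
        if u <= 0 or ch.size != 2:
            raise ValueError("old parent must be a non-root bifurcation")
        sibling = int(ch[ch != seg][0])
        if target in (seg, u, sibling):
            raise ValueError("degenerate splice target")
        parent = self.parent.copy()
        pos = self.pos.copy()
        parent[sibling] = parent[u]
        parent[u] = self.parent[target]
        parent[target] = u
        pos[u] = 0.5 * (self.pos[self.parent[target]] + self.pos[target])
        return VascularTree(pos, parent, self.fixed_depth)

    def remove_node(self, v: int) -> "VascularTree":
        """Delete internal node ``v``, re-parenting its children to its
        parent (the pruning primitive that creates trifurcations)."""
        if v == 0:
            raise ValueError("cannot remove the root node")
        parent = self.parent.copy()
        parent[parent == v] = parent[v]
        keep = np.ones(self.n_nodes, dtype=bool)
        keep[v] = False
        remap = np.cumsum(keep) - 1
        new_parent = remap[parent[keep]]
        new_parent[0] = -1
        return VascularTree(self.pos[keep], new_parent, self.fixed_depth)

    # -- reporting ------------------------------------------------------------
    def pressures_mmhg(self, p_term: float) -> np.ndarray:
        """Absolute node pressures in mm Hg, re-adding the terminal offset."""
        return p_term + self.pressure / units.MMHG_TO_PA

    def validate(self) -> None:
        """Raise if the basic structural invariants are violated."""
        _ = self.order  # connectivity + acyclicity (BFS covers all nodes)
        if self.n_segments != self.n_nodes - 1:
            raise AssertionError("|A| != |V| - 1")
        diff = self.pos[1:] - self.pos[self.parent[1:]]
        if not np.allclose(self.length[1:], np.linalg.norm(diff, axis=1), atol=1e-12):
            raise AssertionError("lengths out of sync with positions")

    def __repr__(self) -> str:  # pragma: no cover
        return (f"VascularTree(n_nodes={self.n_nodes}, n_leaves={self.n_leaves}, "
                f"fixed_depth={self.fixed_depth})")
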