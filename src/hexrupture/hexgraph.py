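"""Periodic honeycomb networks and their topology/geometry queries.

A :class:`PeriodicGraph` is the abstract representation of a trivalent
biopolymer network: each node is a cross-linking site and each edge is one
~300 nm network-forming molecule.  Graphs live in a rectangular box that may
be periodic along either axis.  Because the generated lattices are genuinely
toroidal (a 1x1 cell has parallel edges that wrap differently around the
torus), every edge carries an explicit integer image-shift vector for its
second endpoint; displacements are therefore exact and never rely on a
minimum-image guess.

Faces ("polygons"/"rings") are enumerated with a combinatorial-map walk:
half-edges at each node are ordered by bearing and each face is an orbit of
the next-half-edge permutation.  On a fully periodic 2-connected graph the
walks satisfy the torus Euler relation V - E + F = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Box",
    "PeriodicGraph",
    "FaceList",
    "generate_hexagonal",
    "enumerate_faces",
    "interior_face_mask",
    "mean_coordination",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
]


@dataclass(frozen=True)
class Box:
    """Rectangular simulation box with per-axis periodicity flags."""

    lengths: tuple[float, float]
    periodic: tuple[bool, bool] = (True, True)

    @property
    def lx(self) -> float:
        return self.lengths[0]

    @property
    def ly(self) -> float:
        return self.lengths[1]


def _canonical_edges(edges: np.ndarray, shifts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orient every edge so that u <= v, negating the shift on a swap."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2).copy()
    shifts = np.asarray(shifts, dtype=np.int64).reshape(-1, 2).copy()
    flip = edges[:, 0] > edges[:, 1]
    edges[flip] = edges[flip][:, ::-1]
    shifts[flip] = -shifts[flip]
    return edges, shifts


@dataclass
class PeriodicGraph:
    """A planar network in a (possibly periodic) rectangular box.

    Parameters
    ----------
    nodes
        Integer node ids, in a fixed order that defines the row index of
        ``positions``.
    positions
        ``(n, 2)`` coordinates inside the box (graph units; 1.0 is one edge
        length for freshly generated lattices).
    edges
        ``(m, 2)`` node-id pairs, canonicalised so ``u <= v``.
    shifts
        ``(m, 2)`` integer periodic image of the second endpoint relative to
        the first: the edge vector is ``pos[v] + shifts @ L - pos[u]``.
    box
        Box lengths and periodicity flags.
    """

    nodes: np.ndarray
    positions: np.ndarray
    edges: np.ndarray
    shifts: np.ndarray
    box: Box

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.int64).reshape(-1)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if len(self.edges) == 0:
            self.edges = np.zeros((0, 2), dtype=np.int64)
            self.shifts = np.zeros((0, 2), dtype=np.int64)
        else:
            self.edges, self.shifts = _canonical_edges(self.edges, self.shifts)
        self._index = {int(n): i for i, n in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node ids")

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def position_of(self, node_id: int) -> np.ndarray:
        return self.positions[self.index_of(node_id)]

    def degrees(self) -> dict[int, int]:
        deg = {int(n): 0 for n in self.nodes}
        for u, v in self.edges:
            deg[int(u)] += 1
            deg[int(v)] += 1
        return deg

    def edge_vectors(self) -> np.ndarray:
        """Exact displacement of each edge (from u to v's recorded image)."""
        if self.n_edges == 0:
            return np.zeros((0, 2))
        iu = np.fromiter((self._index[int(u)] for u in self.edges[:, 0]), dtype=np.int64)
        iv = np.fromiter((self._index[int(v)] for v in self.edges[:, 1]), dtype=np.int64)
        L = np.asarray(self.box.lengths)
        return self.positions[iv] + self.shifts * L - self.positions[iu]

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(), axis=1)

    def adjacency(self) -> dict[int, list[tuple[int, int, int]]]:
        """Per node id: list of (neighbour id, edge index, direction).

        direction is +1 if the node is the edge's first endpoint, -1 if the
        second (the edge vector then points *towards* the node).
        """
        adj: dict[int, list[tuple[int, int, int]]] = {int(n): [] for n in self.nodes}
        for e, (u, v) in enumerate(self.edges):
            adj[int(u)].append((int(v), e, +1))
            adj[int(v)].append((int(u), e, -1))
        return adj

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loop present")
        key = [(int(u), int(v), int(sx), int(sy))
               for (u, v), (sx, sy) in zip(self.edges, self.shifts)]
        if len(set(key)) != len(key):
            raise ValueError("duplicate edge present")
        for u in self.edges.ravel():
            if int(u) not in self._index:
                raise ValueError(f"edge references unknown node {u}")

    def copy(self) -> "PeriodicGraph":
        return PeriodicGraph(self.nodes.copy(), self.positions.copy(),
                             self.edges.copy(), self.shifts.copy(), self.box)

    # -- editing helpers (used by the defect operations) ---------------

    def without_edges(self, edge_indices) -> "PeriodicGraph":
        keep = np.ones(self.n_edges, dtype=bool)
        keep[np.asarray(list(edge_indices), dtype=np.int64)] = False
        return PeriodicGraph(self.nodes.copy(), self.positions.copy(),
                             self.edges[keep], self.shifts[keep], self.box)

    def without_nodes(self, node_ids) -> "PeriodicGraph":
        drop = {int(n) for n in node_ids}
        keep_nodes = np.array([int(n) not in drop for n in self.nodes])
        keep_edges = np.array([int(u) not in drop and int(v) not in drop
                               for u, v in self.edges], dtype=bool)
        if self.n_edges == 0:
            keep_edges = np.zeros(0, dtype=bool)
        return PeriodicGraph(self.nodes[keep_nodes], self.positions[keep_nodes],
                             self.edges[keep_edges], self.shifts[keep_edges], self.box)

    def with_positions(self, positions: np.ndarray) -> "PeriodicGraph":
        return PeriodicGraph(self.nodes.copy(), np.asarray(positions, dtype=float),
                             self.edges.copy(), self.shifts.copy(), self.box)

    def to_networkx(self):
        """Topology-only multigraph view (edge keys are edge indices)."""
        import networkx as nx

        g = nx.MultiGraph()
        g.add_nodes_from(int(n) for n in self.nodes)
        for e, (u, v) in enumerate(self.edges):
            g.add_edge(int(u), int(v), key=e)
        return g


@dataclass
class FaceList:
    """All closed walks of a planar embedding.

    ``faces[i]`` is the node-id walk, ``face_edges[i]`` the edge indices
    traversed (a bridge edge can appear twice in one walk), ``sizes[i]`` the
    number of half-edges and ``windings[i]`` the signed sum of image shifts
    around the walk (nonzero for walks that wrap a periodic axis).
    """

    faces: list[list[int]]
    face_edges: list[list[int]]
    sizes: np.ndarray
    windings: np.ndarray

    def __len__(self) -> int:
        return len(self.faces)

    def faces_of_edge(self, edge_index: int) -> list[int]:
        return [f for f, es in enumerate(self.face_edges) if edge_index in es]


def generate_hexagonal(nx: int, ny: int, edge_length: float = 1.0) -> PeriodicGraph:
    """Generate a fully periodic honeycomb lattice.

    Uses a rectangular 4-node unit cell with the armchair axis along x, so
    the periodic box is ``(3 a nx, sqrt(3) a ny)`` and every node has
    coordination 3.  4 nodes and 6 edges per cell.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    a = float(edge_length)
    s3 = math.sqrt(3.0)
    # in-cell fractional positions of the 4 basis nodes
    basis = np.array([[0.0, 0.0], [0.5, s3 / 2], [1.5, s3 / 2], [2.0, 0.0]])

    nodes = np.arange(4 * nx * ny, dtype=np.int64)
    positions = np.empty((4 * nx * ny, 2))
    edges = []
    shifts = []

    def nid(ix: int, iy: int, b: int) -> int:
        return 4 * ((iy % ny) * nx + (ix % nx)) + b

    for iy in range(ny):
        for ix in range(nx):
            base = 4 * (iy * nx + ix)
            origin = np.array([3.0 * ix, s3 * iy])
            positions[base:base + 4] = (origin + basis) * a
            # in-cell chain
            for b in range(3):
                edges.append((base + b, base + b + 1))
                shifts.append((0, 0))
            # to the +x neighbour cell: node 3 -> node 0
            edges.append((base + 3, nid(ix + 1, iy, 0)))
            shifts.append(((ix + 1) // nx, 0))
            # to the +y neighbour cell: node 1 -> node 0 and node 2 -> node 3
            edges.append((base + 1, nid(ix, iy + 1, 0)))
            shifts.append((0, (iy + 1) // ny))
            edges.append((base + 2, nid(ix, iy + 1, 3)))
            shifts.append((0, (iy + 1) // ny))

    g = PeriodicGraph(nodes, positions,
                      np.array(edges), np.array(shifts),
                      Box((3.0 * a * nx, s3 * a * ny), (True, True)))
    g.validate()
    return g


def mean_coordination(g: PeriodicGraph) -> float:
    """Mean node coordination number <k> = 2E / V."""
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    return 2.0 * g.n_edges / g.n_nodes


def _sorted_half_edges(g: PeriodicGraph, tol: float = 1e-9):
    """Per node: outgoing half-edges sorted counter-clockwise by bearing.

    A half-edge is ``2*e + d`` where d=0 traverses edge e forwards (u->v)
    and d=1 backwards.  Raises on coincident bearings (degenerate embedding).
    """
    vecs = g.edge_vectors()
    order: dict[int, list[int]] = {int(n): [] for n in g.nodes}
    bearing: dict[int, float] = {}
    for e, (u, v) in enumerate(g.edges):
        ang = math.atan2(vecs[e, 1], vecs[e, 0])
        bearing[2 * e] = ang
        bearing[2 * e + 1] = math.atan2(-vecs[e, 1], -vecs[e, 0])
        order[int(u)].append(2 * e)
        order[int(v)].append(2 * e + 1)
    for n, hs in order.items():
        hs.sort(key=lambda h: bearing[h])
        for h1, h2 in zip(hs, hs[1:]):
            if abs(bearing[h1] - bearing[h2]) < tol:
                raise ValueError(
                    f"degenerate embedding: coincident neighbour bearings at node {n}")
    return order


def enumerate_faces(g: PeriodicGraph) -> FaceList:
    """Enumerate all closed walks (faces) of the embedded graph.

    At each node the incident half-edges are ordered by bearing; a face walk
    leaves along the half-edge that is next *clockwise* from the reversal of
    the arriving half-edge.  Every half-edge belongs to exactly one walk, so
    the face sizes always sum to 2E.
    """
    order = _sorted_half_edges(g)
    # position of each half-edge in its tail node's CCW order
    pos_in_order: dict[int, tuple[int, int]] = {}
    for n, hs in order.items():
        for i, h in enumerate(hs):
            pos_in_order[h] = (n, i)

    def tail(h: int) -> int:
        e, d = divmod(h, 2)
        return int(g.edges[e, d])

    def head(h: int) -> int:
        e, d = divmod(h, 2)
        return int(g.edges[e, 1 - d])

    def nxt(h: int) -> int:
        twin = h ^ 1
        n, i = pos_in_order[twin]
        hs = order[n]
        return hs[(i - 1) % len(hs)]

    seen = set()
    faces, face_edges, sizes, windings = [], [], [], []
    all_half_edges = sorted(pos_in_order)
    for h0 in all_half_edges:
        if h0 in seen:
            continue
        walk_nodes, walk_edges = [], []
        wind = np.zeros(2, dtype=np.int64)
        h = h0
        while True:
            seen.add(h)
            e, d = divmod(h, 2)
            walk_nodes.append(tail(h))
            walk_edges.append(e)
            wind += g.shifts[e] * (1 if d == 0 else -1)
            h = nxt(h)
            if h == h0:
                break
        faces.append(walk_nodes)
        face_edges.append(walk_edges)
        sizes.append(len(walk_edges))
        windings.append(wind)
    return FaceList(faces, face_edges,
                    np.array(sizes, dtype=np.int64),
                    np.array(windings, dtype=np.int64).reshape(-1, 2))


def interior_face_mask(g: PeriodicGraph, fl: FaceList) -> np.ndarray:
    """Boolean mask of the interior polygons among all closed walks.

    Fully periodic graphs: every walk is interior.  One periodic axis: walks
    that wind around the periodic axis are boundary walks.  Non-periodic
    graphs: the single largest-perimeter walk is the unbounded outer face.
    """
    n = len(fl)
    mask = np.ones(n, dtype=bool)
    if n == 0:
        return mask
    px, py = g.box.periodic
    if px and py:
        return mask
    if px or py:
        axis = 0 if px else 1
        mask &= fl.windings[:, axis] == 0
        return mask
    mask[int(np.argmax(fl.sizes))] = False
    return mask


# -- file formats ------------------------------------------------------


def write_edgelist(g: PeriodicGraph, path) -> None:
    """Plain-text graph format: box line, node block, edge block."""
    with open(path, "w") as f:
        f.write(f"box {g.box.lx!r} {g.box.ly!r} "
                f"{int(g.box.periodic[0])} {int(g.box.periodic[1])}\n")
        for n, (x, y) in zip(g.nodes, g.positions):
            f.write(f"node {int(n)} {float(x)!r} {float(y)!r}\n")
        for (u, v), (sx, sy) in zip(g.edges, g.shifts):
            f.write(f"edge {int(u)} {int(v)} {int(sx)} {int(sy)}\n")


def read_edgelist(path) -> PeriodicGraph:
    nodes, positions, edges, shifts = [], [], [], []
    box = None
    with open(path) as f:
        for line in f:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "box":
                box = Box((float(parts[1]), float(parts[2])),
                          (bool(int(parts[3])), bool(int(parts[4]))))
            elif parts[0] == "node":
                nodes.append(int(parts[1]))
                positions.append((float(parts[2]), float(parts[3])))
            elif parts[0] == "edge":
                edges.append((int(parts[1]), int(parts[2])))
                shifts.append((int(parts[3]), int(parts[4])))
            else:
                raise ValueError(f"unknown record {parts[0]!r}")
    if box is None:
        raise ValueError("missing box record")
    return PeriodicGraph(np.array(nodes, dtype=np.int64),
                         np.array(positions, dtype=float).reshape(-1, 2),
                         np.array(edges, dtype=np.int64).reshape(-1, 2),
                         np.array(shifts, dtype=np.int64).reshape(-1, 2), box)


def write_graphml(g: PeriodicGraph, path) -> None:
    import networkx as nx

    gx = nx.MultiGraph(lx=repr(g.box.lx), ly=repr(g.box.ly),
                       px=int(g.box.periodic[0]), py=int(g.box.periodic[1]))
    for n, (x, y) in zip(g.nodes, g.positions):
        gx.add_node(int(n), x=repr(float(x)), y=repr(float(y)))
    for e, ((u, v), (sx, sy)) in enumerate(zip(g.edges, g.shifts)):
        gx.add_edge(int(u), int(v), key=e, sx=int(sx), sy=int(sy))
    nx.write_graphml(gx, path)


def read_graphml(path) -> PeriodicGraph:
    import networkx as nx

    gx = nx.read_graphml(path, node_type=int, force_multigraph=True)
    box = Box((float(gx.graph["lx"]), float(gx.graph["ly"])),
              (bool(int(gx.graph["px"])), bool(int(gx.graph["py"]))))
    nodes = sorted(gx.nodes)
    positions = [(float(gx.nodes[n]["x"]), float(gx.nodes[n]["y"])) for n in nodes]
    edges, shifts = [], []
    for u, v, data in gx.edges(data=True):
        edges.append((u, v))
        shifts.append((int(data["sx"]), int(data["sy"])))
    return PeriodicGraph(np.array(nodes, dtype=np.int64),
                         np.array(positions, dtype=float).reshape(-1, 2),
                         np.array(edges, dtype=np.int64).reshape(-1, 2),
                         np.array(shifts, dtype=np.int64).reshape(-1, 2), box)
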