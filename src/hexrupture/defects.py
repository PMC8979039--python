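"""Reproducible defect introduction for periodic networks.

Four kinds of well-defined damage are supported, mirroring how real
network-forming collagen assemblies go wrong:

* random edge removal (missing molecules) followed by recursive pruning of
  dangling ends,
* Stone-Wales style bond switches (a misplaced molecule: one edge rotation
  that turns four hexagons into two pentagons and two heptagons),
* topological holes (surgical damage: remove a node and everything within a
  breadth-first distance),
* thin periodic strips (the limit of an infinitely large hole).

All operations are deterministic under a fixed seed, and a
:class:`DefectRecipe` records an ordered list of operations so that a whole
defect structure can be replayed or serialised.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import graph_energy
from .hexgraph import Box, PeriodicGraph, enumerate_faces, generate_hexagonal

__all__ = [
    "DefectRecipe",
    "remove_random_edges",
    "prune_dangling",
    "bond_switch",
    "cut_hole",
    "topological_ball",
    "hole_boundary_nodes",
    "make_strip",
    "apply_recipe",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def prune_dangling(g: PeriodicGraph) -> PeriodicGraph:
    """Recursively remove k = 1 nodes (and k = 0 leftovers); idempotent."""
    edges = [tuple(int(x) for x in e) for e in g.edges]
    alive_edge = [True] * len(edges)
    deg: dict[int, int] = {int(n): 0 for n in g.nodes}
    incident: dict[int, list[int]] = {int(n): [] for n in g.nodes}
    for i, (u, v) in enumerate(edges):
        deg[u] += 1
        deg[v] += 1
        incident[u].append(i)
        incident[v].append(i)
    queue = deque(n for n, d in deg.items() if d == 1)
    while queue:
        n = queue.popleft()
        if deg[n] != 1:
            continue
        for i in incident[n]:
            if not alive_edge[i]:
                continue
            alive_edge[i] = False
            u, v = edges[i]
            for m in (u, v):
                deg[m] -= 1
                if deg[m] == 1:
                    queue.append(m)
    keep_edges = np.array(alive_edge, dtype=bool)
    dead_nodes = [n for n, d in deg.items() if d == 0]
    out = PeriodicGraph(g.nodes.copy(), g.positions.copy(),
                        g.edges[keep_edges] if len(edges) else g.edges,
                        g.shifts[keep_edges] if len(edges) else g.shifts, g.box)
    if dead_nodes:
        out = out.without_nodes(dead_nodes)
    return out


def remove_random_edges(g: PeriodicGraph, fraction: float = 0.0, seed=None,
                        edge_indices=None, n_edges: int | None = None) -> PeriodicGraph:
    """Delete ceil(fraction * E) randomly chosen edges, then prune.

    ``n_edges`` gives an explicit count instead of a fraction.
    ``edge_indices`` overrides the random choice (used by progressive-removal
    recipes, which remove prefixes of one fixed permutation so that larger
    fractions remove supersets of smaller ones).
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    if edge_indices is None:
        n_remove = math.ceil(fraction * g.n_edges) if n_edges is None else int(n_edges)
        if n_remove >= g.n_edges:
            raise ValueError("cannot remove every edge")
        if n_remove == 0:
            return g.copy()
        rng = _rng(seed)
        edge_indices = rng.choice(g.n_edges, size=n_remove, replace=False)
    elif len(edge_indices) == 0:
        return g.copy()
    return prune_dangling(g.without_edges(edge_indices))


def bond_switch(g: PeriodicGraph, seed=None, max_attempts: int = 100,
                relax: bool = True, pot: graph_energy.GraphPotential | None = None,
                relax_radius: int = 3, edge_candidates=None) -> PeriodicGraph:
    """One Stone-Wales bond switch with rejection resampling.

    Picks a random edge (u, v), then neighbours a of u and b of v with
    a, b, u, v all distinct and the edges (a, u) and (v, b) in different
    polygons; deletes (a, u) and (v, b) and adds (a, v) and (u, b).  Node
    degrees are preserved.  The neighbourhood is locally relaxed afterwards.
    """
    rng = _rng(seed)
    faces = enumerate_faces(g)
    adj = g.adjacency()

    # map canonical (u, v, s) -> edge index for duplicate detection
    existing = {(int(u), int(v), int(sx), int(sy))
                for (u, v), (sx, sy) in zip(g.edges, g.shifts)}

    def canon(u, v, s):
        if u > v:
            return (v, u, -s[0], -s[1])
        return (u, v, s[0], s[1])

    if edge_candidates is None:
        edge_candidates = np.arange(g.n_edges)
    else:
        edge_candidates = np.asarray(list(edge_candidates), dtype=np.int64)
    for _ in range(max_attempts):
        e_uv = int(edge_candidates[int(rng.integers(len(edge_candidates)))])
        u, v = (int(x) for x in g.edges[e_uv])
        s_uv = g.shifts[e_uv].copy()
        # orient: shift of v relative to u
        nb_u = [(n, e, d) for (n, e, d) in adj[u] if e != e_uv]
        nb_v = [(n, e, d) for (n, e, d) in adj[v] if e != e_uv]
        if not nb_u or not nb_v:
            continue
        a, e_au, d_au = nb_u[int(rng.integers(len(nb_u)))]
        b, e_vb, d_vb = nb_v[int(rng.integers(len(nb_v)))]
        if len({a, b, u, v}) != 4:
            continue
        # the two sacrificial edges must lie in different polygons
        if set(faces.faces_of_edge(e_au)) & set(faces.faces_of_edge(e_vb)):
            continue
        # shifts relative to the canonical edge orientation:
        # s(u->a) and s(v->b)
        s_ua = g.shifts[e_au] * (1 if d_au == 1 else -1)
        s_vb = g.shifts[e_vb] * (1 if d_vb == 1 else -1)
        # new edges: (a, v) with s(a->v) = -s(u->a) + s(u->v); (u, b) with
        # s(u->b) = s(u->v) + s(v->b)
        s_av = -s_ua + s_uv
        s_ub = s_uv + s_vb
        new1 = canon(a, v, (int(s_av[0]), int(s_av[1])))
        new2 = canon(u, b, (int(s_ub[0]), int(s_ub[1])))
        if new1 in existing or new2 in existing or new1 == new2:
            continue
        keep = np.ones(g.n_edges, dtype=bool)
        keep[[e_au, e_vb]] = False
        edges = np.vstack([g.edges[keep], [[new1[0], new1[1]], [new2[0], new2[1]]]])
        shifts = np.vstack([g.shifts[keep], [[new1[2], new1[3]], [new2[2], new2[3]]]])
        out = PeriodicGraph(g.nodes.copy(), g.positions.copy(), edges, shifts, g.box)
        out.validate()
        if relax:
            out = _relax_local(out, {a, b, u, v}, pot, relax_radius)
        return out
    raise RuntimeError(f"no admissible bond switch found in {max_attempts} attempts")


def _relax_local(g: PeriodicGraph, region_nodes, pot, radius: int) -> PeriodicGraph:
    """Relax nodes within topological distance ``radius`` of the region."""
    pot = pot or graph_energy.GraphPotential()
    free = set()
    dist = {int(n): 0 for n in region_nodes if int(n) in g._index}
    queue = deque(dist)
    adj = g.adjacency()
    while queue:
        n = queue.popleft()
        free.add(n)
        if dist[n] >= radius:
            continue
        for m, _, _ in adj[n]:
            if m not in dist:
                dist[m] = dist[n] + 1
                queue.append(m)
    frozen = [int(n) for n in g.nodes if int(n) not in free]
    return graph_energy.relax(g, pot, frozen=frozen).graph


def topological_ball(g: PeriodicGraph, center_node: int, radius: int) -> set[int]:
    """Node ids within breadth-first (topological) distance <= radius."""
    center_node = int(center_node)
    if center_node not in g._index:
        raise ValueError(f"node {center_node} not in graph")
    adj = g.adjacency()
    dist = {center_node: 0}
    queue = deque([center_node])
    while queue:
        n = queue.popleft()
        if dist[n] >= radius:
            continue
        for m, _, _ in adj[n]:
            if m not in dist:
                dist[m] = dist[n] + 1
                queue.append(m)
    return set(dist)


def hole_boundary_nodes(g: PeriodicGraph, center_node: int, radius: int) -> set[int]:
    """Surviving nodes adjacent to the removed ball (computed pre-cut)."""
    ball = topological_ball(g, center_node, radius)
    adj = g.adjacency()
    boundary = set()
    for n in ball:
        for m, _, _ in adj[n]:
            if m not in ball:
                boundary.add(m)
    return boundary


def cut_hole(g: PeriodicGraph, center_node: int, radius: int,
             relax: bool = True, pot: graph_energy.GraphPotential | None = None,
             relax_radius: int = 3) -> PeriodicGraph:
    """Remove all nodes within topological distance ``radius`` of the centre.

    Incident edges go with them; dangling remnants are pruned and the hole
    rim is locally relaxed.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    ball = topological_ball(g, center_node, radius)
    if len(ball) >= g.n_nodes:
        raise ValueError("hole would cover the entire graph")
    boundary = hole_boundary_nodes(g, center_node, radius)
    out = prune_dangling(g.without_nodes(ball))
    if out.n_nodes == 0:
        raise ValueError("hole removal left an empty graph")
    if relax:
        out = _relax_local(out, boundary & {int(n) for n in out.nodes}, pot, relax_radius)
    return out


def make_strip(n_cells: int, width_rows: int, edge_length: float = 1.0) -> PeriodicGraph:
    """Thin honeycomb strip: periodic along y, free boundaries along x.

    ``n_cells`` unit cells repeat along the periodic y axis; ``width_rows``
    rows of hexagons span the finite x direction.  Boundary nodes have k = 2
    but never k = 1.
    """
    if width_rows < 1:
        raise ValueError("width_rows must be >= 1")
    g = generate_hexagonal(nx=width_rows, ny=n_cells, edge_length=edge_length)
    crossing = np.where(g.shifts[:, 0] != 0)[0]
    cut = g.without_edges(crossing)
    cut = PeriodicGraph(cut.nodes, cut.positions, cut.edges, cut.shifts,
                        Box(g.box.lengths, (False, True)))
    return prune_dangling(cut)


@dataclass
class DefectRecipe:
    """Ordered, seeded list of defect operations.

    Each operation is a mapping with a ``kind`` key in
    ``{"remove_edges", "bond_switch", "hole", "strip"}`` plus its
    parameters (``fraction``, ``n`` switches, ``center``/``radius``, ...).
    ``progressive`` makes edge removals draw prefixes of one fixed
    permutation, so a larger fraction removes a superset of a smaller one.
    """

    operations: list[dict] = field(default_factory=list)
    seed: int = 0
    correlated: bool = False
    progressive: bool = False

    _KINDS = {"remove_edges", "bond_switch", "hole", "strip"}

    def __post_init__(self) -> None:
        for op in self.operations:
            kind = op.get("kind")
            if kind not in self._KINDS:
                raise ValueError(f"unknown defect kind {kind!r}")
            if kind == "remove_edges":
                f = float(op.get("fraction", 0.0))
                if not (0.0 <= f < 1.0):
                    raise ValueError("remove_edges fraction must be in [0, 1)")
            if kind == "hole" and int(op.get("radius", 0)) < 0:
                raise ValueError("hole radius must be >= 0")
            if kind == "strip" and int(op.get("width_rows", 1)) < 1:
                raise ValueError("strip width_rows must be >= 1")

    def to_dict(self) -> dict:
        return {"operations": [dict(op) for op in self.operations],
                "seed": self.seed, "correlated": self.correlated,
                "progressive": self.progressive}

    @classmethod
    def from_dict(cls, d: dict) -> "DefectRecipe":
        known = {"operations", "seed", "correlated", "progressive"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown recipe keys: {sorted(unknown)}")
        return cls(operations=list(d.get("operations", [])),
                   seed=int(d.get("seed", 0)),
                   correlated=bool(d.get("correlated", False)),
                   progressive=bool(d.get("progressive", False)))


def apply_recipe(g: PeriodicGraph, recipe: DefectRecipe) -> tuple[PeriodicGraph, dict]:
    """Apply a recipe; returns (graph, provenance).

    Provenance records, per operation, what was removed or switched —
    notably the hole boundary node set needed to classify later break
    events as rim vs bulk damage.
    """
    rng = np.random.default_rng(recipe.seed)
    prov: dict = {"operations": []}
    out = g
    perm = None
    removed_so_far = 0
    last_region: set[int] = set()

    def near_edge_candidates(graph, distance=3):
        """Edge indices with an endpoint near the previous defect (or all)."""
        region = {int(n) for n in last_region if int(n) in graph._index}
        if not recipe.correlated or not region:
            return None
        near = set(region)
        for n in region:
            near |= topological_ball(graph, n, distance)
        cand = [i for i, (u, v) in enumerate(graph.edges)
                if int(u) in near or int(v) in near]
        return cand or None

    for op in recipe.operations:
        kind = op["kind"]
        if kind == "remove_edges":
            fraction = float(op.get("fraction", 0.0))
            if "n" in op or (recipe.correlated and not recipe.progressive):
                n_remove = int(op["n"]) if "n" in op \
                    else math.ceil(fraction * out.n_edges)
                before = out.n_edges
                cand = near_edge_candidates(out)
                if cand is not None and len(cand) >= n_remove:
                    idx = rng.choice(len(cand), size=n_remove, replace=False)
                    chosen = [cand[i] for i in idx]
                    last_region = {int(x) for e in chosen
                                   for x in out.edges[e]}
                    out = remove_random_edges(out, edge_indices=chosen)
                else:
                    chosen = rng.choice(out.n_edges, size=n_remove,
                                        replace=False)
                    last_region = {int(x) for e in chosen
                                   for x in out.edges[e]}
                    out = remove_random_edges(out, edge_indices=chosen)
                prov["operations"].append(
                    {"kind": kind, "removed": n_remove,
                     "pruned": before - n_remove - out.n_edges})
            elif recipe.progressive:
                if perm is None:
                    perm = rng.permutation(out.n_edges)
                n_remove = math.ceil(fraction * len(perm))
                idx = perm[removed_so_far:n_remove]
                # map permutation indices (over the original edge array) to
                # current indices by edge identity
                current = {(int(u), int(v), int(sx), int(sy)): i
                           for i, ((u, v), (sx, sy))
                           in enumerate(zip(out.edges, out.shifts))}
                keys = [(int(u), int(v), int(sx), int(sy))
                        for (u, v), (sx, sy) in zip(g.edges, g.shifts)]
                drop = [current[keys[i]] for i in idx if keys[i] in current]
                removed_so_far = max(removed_so_far, n_remove)
                out = remove_random_edges(out, fraction, edge_indices=drop)
                prov["operations"].append({"kind": kind, "removed": len(drop)})
            else:
                before = out.n_edges
                removed = {tuple(map(int, np.r_[e, s]))
                           for e, s in zip(out.edges, out.shifts)}
                out = remove_random_edges(out, fraction, seed=rng)
                removed -= {tuple(map(int, np.r_[e, s]))
                            for e, s in zip(out.edges, out.shifts)}
                last_region = {k[0] for k in removed} | {k[1] for k in removed}
                prov["operations"].append(
                    {"kind": kind,
                     "removed": math.ceil(fraction * before),
                     "pruned": before - math.ceil(fraction * before) - out.n_edges})
        elif kind == "bond_switch":
            n = int(op.get("n", 1))
            for _ in range(n):
                old = {tuple(map(int, np.r_[e, s]))
                       for e, s in zip(out.edges, out.shifts)}
                out = bond_switch(out, seed=rng,
                                  edge_candidates=near_edge_candidates(out))
                new = {tuple(map(int, np.r_[e, s]))
                       for e, s in zip(out.edges, out.shifts)}
                changed = old ^ new
                last_region = {k[0] for k in changed} | {k[1] for k in changed}
            prov["operations"].append({"kind": kind, "n": n})
        elif kind == "hole":
            center = op.get("center")
            if center is None:
                region = sorted(int(n) for n in last_region
                                if int(n) in out._index)
                if recipe.correlated and region:
                    center = int(region[int(rng.integers(len(region)))])
                else:
                    center = int(out.nodes[int(rng.integers(out.n_nodes))])
            radius = int(op.get("radius", 0))
            boundary = hole_boundary_nodes(out, center, radius)
            out = cut_hole(out, center, radius)
            last_region = set(boundary)
            prov["operations"].append({"kind": kind, "center": int(center),
                                       "radius": radius,
                                       "boundary": sorted(boundary)})
        elif kind == "strip":
            out = make_strip(int(op["n_cells"]), int(op.get("width_rows", 1)))
            prov["operations"].append({"kind": kind})
    return out, prov
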