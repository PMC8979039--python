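"""Damage metrics for bead systems and trajectories.

The central object is the *effective graph*: head beads are clustered by
single linkage (one cluster per surviving cross-link node) and every
molecule whose five Morse bonds are all intact contributes an edge between
the clusters holding its two heads.  On an undamaged system this round-trips
to the source network exactly; as bonds break the effective graph loses
edges, its mean coordination <k> drops from 3 towards 1 (a fully detached
but intact molecule is an isolated edge whose endpoints have degree 1), and
its face statistics pick up the merged polygons that a tear leaves behind.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hexgraph import Box, PeriodicGraph, enumerate_faces, interior_face_mask
from .polymerize import BeadSystem, head_clusters

__all__ = [
    "BreakEvent",
    "DamageTrajectory",
    "fraction_broken",
    "effective_graph",
    "network_coordination",
    "edges_per_polygon",
    "time_to_first_damage",
    "msd",
    "classify_break_location",
    "aggregate",
    "rupture_onset",
    "system_at",
    "system_at_time",
]


@dataclass
class BreakEvent:
    """One irreparable (Morse-bond) break."""

    time: float                 # ns
    bond_index: int
    beads: tuple[int, int]
    molecule_id: int            # molecule label just before the break
    source_molecule: int        # immutable source-graph edge index
    position: tuple[float, float]   # bond midpoint at break, nm
    location_class: str | None = None


@dataclass
class DamageTrajectory:
    """Sampled time series of a single deformation run.

    ``n_broken`` is the fraction of initially present Morse bonds that have
    been deleted (0 intact, 1 nothing left); it is non-decreasing by
    construction.  ``msd`` is the mean square *non-affine* displacement per
    bead (the imposed box stretch is divided out before comparing with the
    initial positions), so purely affine motion gives zero.  ``frames``
    optionally stores bead positions at each sample for post-hoc structural
    metrics.
    """

    times: np.ndarray
    n_broken: np.ndarray
    box_lx: np.ndarray
    msd: np.ndarray
    events: list[BreakEvent]
    initial_system: BeadSystem
    frames: list[np.ndarray] | None = None
    _mean_k_cache: np.ndarray | None = field(default=None, repr=False)

    def mean_k(self, cluster_cutoff: float | None = None) -> np.ndarray:
        """Mean effective coordination <k>(t) at every sample (needs frames)."""
        if self._mean_k_cache is not None and cluster_cutoff is None:
            return self._mean_k_cache
        if self.frames is None:
            raise ValueError("trajectory was recorded without frames")
        out = np.array([network_coordination(system_at(self, i), cluster_cutoff)
                        for i in range(len(self.times))])
        if cluster_cutoff is None:
            self._mean_k_cache = out
        return out

    def to_dataframe(self, include_mean_k: bool = False) -> pd.DataFrame:
        data = {"time_ns": self.times, "n_broken": self.n_broken,
                "box_lx_nm": self.box_lx, "msd_nm2": self.msd}
        if include_mean_k:
            data["mean_k"] = self.mean_k()
        return pd.DataFrame(data)

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"time_ns": e.time, "bead_i": e.beads[0], "bead_j": e.beads[1],
              "x_nm": e.position[0], "y_nm": e.position[1],
              "bond_index": e.bond_index, "source_molecule": e.source_molecule,
              "location_class": e.location_class or ""}
             for e in self.events])


def system_at(traj: DamageTrajectory, sample_index: int) -> BeadSystem:
    """Reconstruct the bead system at a sampled time from frames + events."""
    return system_at_time(traj, float(traj.times[sample_index]),
                          _frame_index=sample_index)


def system_at_time(traj: DamageTrajectory, t: float,
                   _frame_index: int | None = None) -> BeadSystem:
    """Reconstruct the state at an arbitrary time within the run.

    The bond/angle state is exact (events up to and including ``t``);
    positions and box come from the last stored frame at or before ``t``.
    """
    if traj.frames is None:
        raise ValueError("trajectory was recorded without frames")
    if _frame_index is None:
        _frame_index = max(0, int(np.searchsorted(traj.times, t, side="right")) - 1)
    sys = traj.initial_system.copy()
    sys.positions = np.asarray(traj.frames[_frame_index], dtype=float)
    for e in traj.events:
        if e.time <= t:
            sys.bond_alive[e.bond_index] = False
    dead = ~sys.bond_alive[sys.angle_bonds]
    sys.angle_alive = ~np.any(dead, axis=1)
    sys.box = Box((float(traj.box_lx[_frame_index]), sys.box.ly), sys.box.periodic)
    return sys


def fraction_broken(obj) -> float:
    """Fraction of the initial Morse bonds now deleted."""
    if isinstance(obj, DamageTrajectory):
        return float(obj.n_broken[-1])
    sys: BeadSystem = obj
    if sys.n_bonds_initial == 0:
        raise ValueError("system has no bonds")
    return 1.0 - sys.n_bonds_alive / sys.n_bonds_initial


def _molecule_intact(sys: BeadSystem) -> np.ndarray:
    """Per source molecule: True if its 5-bond chain is fully alive."""
    E = sys.n_bonds_initial // 5
    return np.all(sys.bond_alive.reshape(E, 5), axis=1)


def effective_graph(sys: BeadSystem, cluster_cutoff: float | None = None,
                    deduplicate: bool = False) -> PeriodicGraph:
    """Reconstructed network: head clusters as nodes, intact molecules as edges.

    ``deduplicate`` merges parallel edges and drops self-loops, which the
    face enumeration requires; coordination counts keep every molecule.
    """
    clusters = head_clusters(sys, cluster_cutoff)
    n_clusters = len(clusters)
    cluster_of = {}
    centroids = np.empty((n_clusters, 2))
    for c, members in enumerate(clusters):
        ref = sys.positions[members[0]]
        disp = sys.min_image(sys.positions[members] - ref)
        centroids[c] = ref + disp.mean(axis=0)
        for b in members:
            cluster_of[int(b)] = c

    intact = _molecule_intact(sys)
    L = np.asarray(sys.box.lengths)
    edges, shifts = [], []
    for e in np.where(intact)[0]:
        h1, h2 = 6 * e, 6 * e + 5
        c1, c2 = cluster_of[h1], cluster_of[h2]
        d = centroids[c2] - centroids[c1]
        s = np.zeros(2, dtype=np.int64)
        for ax in range(2):
            if sys.box.periodic[ax]:
                s[ax] = -int(np.rint(d[ax] / L[ax]))
        edges.append((c1, c2))
        shifts.append((int(s[0]), int(s[1])))
    edges = np.array(edges, dtype=np.int64).reshape(-1, 2)
    shifts = np.array(shifts, dtype=np.int64).reshape(-1, 2)
    g = PeriodicGraph(np.arange(n_clusters, dtype=np.int64), centroids,
                      edges, shifts, sys.box)
    if deduplicate and g.n_edges:
        keep, seen = [], set()
        for i, ((u, v), (sx, sy)) in enumerate(zip(g.edges, g.shifts)):
            key = (int(u), int(v), int(sx), int(sy))
            if int(u) == int(v) or key in seen:
                continue
            seen.add(key)
            keep.append(i)
        g = PeriodicGraph(g.nodes, g.positions, g.edges[keep], g.shifts[keep], g.box)
    return g


def network_coordination(sys: BeadSystem, cluster_cutoff: float | None = None) -> float:
    """Mean node degree <k> of the reconstructed effective graph."""
    g = effective_graph(sys, cluster_cutoff)
    if g.n_nodes == 0:
        raise ValueError("no head clusters found")
    return 2.0 * g.n_edges / g.n_nodes


def edges_per_polygon(obj, cluster_cutoff: float | None = None,
                      outlier_factor: float = 2.0) -> float:
    """Mean interior face size ("edges per polygon").

    Accepts a :class:`PeriodicGraph` or a :class:`BeadSystem` (reconstructed
    first).  Boundary walks are excluded per the box periodicity; on torn
    systems the voids opened by a tear are additionally excluded as any face
    larger than ``outlier_factor`` times the median interior face size —
    a rupture void spans many hexagons and is not a polygon of the network.
    """
    if isinstance(obj, BeadSystem):
        from .defects import prune_dangling

        # polygons are cycle faces: dangling stubs of a damaged network are
        # not polygon edges, so reduce to the 2-core first
        g = prune_dangling(effective_graph(obj, cluster_cutoff, deduplicate=True))
    else:
        g = obj
    if g.n_edges == 0:
        raise ValueError("no edges, no polygons")
    fl = enumerate_faces(g)
    sizes = fl.sizes[interior_face_mask(g, fl)]
    if len(sizes) == 0:
        raise ValueError("no interior faces")
    if outlier_factor is not None and len(sizes) > 1:
        med = float(np.median(sizes))
        sizes = sizes[sizes <= outlier_factor * med]
    if len(sizes) == 0:
        raise ValueError("no polygonal faces after boundary exclusion")
    return float(np.mean(sizes))


def time_to_first_damage(traj: DamageTrajectory) -> float:
    """Time of the first Morse-bond break; inf if the run stayed intact.

    Head-group separations are repairable and never counted.
    """
    if not traj.events:
        return math.inf
    return min(e.time for e in traj.events)


def msd(traj: DamageTrajectory) -> np.ndarray:
    """Mean square non-affine displacement per bead, at the sample times."""
    return traj.msd


def classify_break_location(event: BreakEvent, sys: BeadSystem,
                            graph: PeriodicGraph, hole_boundary,
                            distance_cutoff: int = 1) -> str:
    """Label a break "edge" (near the hole rim) or "bulk".

    The break's source edge is within the cutoff if either endpoint node is
    within ``distance_cutoff`` (breadth-first distance on ``graph``) of the
    hole-boundary node set.
    """
    boundary = {int(n) for n in hole_boundary}
    if not boundary:
        raise ValueError("no hole boundary given (recipe had no hole?)")
    if sys.source_edges is None:
        raise ValueError("system does not record source edges")
    u, v = (int(x) for x in sys.source_edges[event.source_molecule])
    dist = {n: 0 for n in boundary if n in graph._index}
    queue = deque(dist)
    adj = graph.adjacency()
    while queue:
        n = queue.popleft()
        if dist[n] >= distance_cutoff:
            continue
        for m, _, _ in adj[n]:
            if m not in dist:
                dist[m] = dist[n] + 1
                queue.append(m)
    d = min(dist.get(u, math.inf), dist.get(v, math.inf))
    return "edge" if d <= distance_cutoff else "bulk"


def aggregate(trajs, n_points: int = 200,
              include_mean_k: bool = False) -> pd.DataFrame:
    """Pointwise mean +/- population std of N_broken (and optionally <k>).

    Trajectories are resampled onto a common grid by linear interpolation.
    """
    if len(trajs) < 2:
        raise ValueError("need at least two trajectories to aggregate")
    t0 = max(t.times[0] for t in trajs)
    t1 = min(t.times[-1] for t in trajs)
    grid = np.linspace(t0, t1, n_points)
    nb = np.stack([np.interp(grid, t.times, t.n_broken) for t in trajs])
    out = {"time_ns": grid,
           "n_broken_mean": nb.mean(axis=0),
           "n_broken_std": nb.std(axis=0)}
    if include_mean_k:
        mk = np.stack([np.interp(grid, t.times, t.mean_k()) for t in trajs])
        out["mean_k_mean"] = mk.mean(axis=0)
        out["mean_k_std"] = mk.std(axis=0)
    return pd.DataFrame(out)


def rupture_onset(obj, window: float = 500.0, factor: float = 5.0) -> float:
    """Onset of the bond-breaking cascade that propagates a tear.

    The onset is the first break time at which the *subsequent* break rate
    (events in the ``window`` ns ahead, inclusive) exceeds ``factor`` times
    the run-average rate over all earlier events; at least one earlier event
    is required, so a lone first break never triggers.  If the criterion
    never fires the time of the maximum windowed rate is returned; inf if
    there are no events.
    """
    events = obj.events if isinstance(obj, DamageTrajectory) else obj
    times = np.sort(np.asarray([e.time if isinstance(e, BreakEvent) else e
                                for e in events], dtype=float))
    if len(times) == 0:
        return math.inf
    best_t, best_rate = times[0], -1.0
    for i in range(len(times)):
        t = times[i]
        ahead = np.count_nonzero((times >= t) & (times < t + window))
        rate_w = ahead / window
        if rate_w > best_rate:
            best_rate, best_t = rate_w, t
        if i == 0 or t <= 0:
            continue
        rate_before = i / t
        if rate_w > factor * rate_before:
            return float(t)
    return float(best_t)
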