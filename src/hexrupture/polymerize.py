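"""Convert a relaxed network graph into a coarse-grained bead-spring system.

Each graph edge becomes one six-bead polymer (one ~300 nm tropocollagen-like
molecule): the two end beads are attractive "heads" that cluster with the
heads of the other molecules meeting at a node (a reversible cross-link),
the four interior beads are repulsive "bodies".  Beads are placed along the
edge with the two heads inset half a bond length from the nodes — for the
default 300 nm node spacing and 50 nm equilibrium bond length the bead
arc-length offsets are 25, 75, ..., 275 nm — so consecutive beads sit
exactly at the Morse equilibrium distance and the three heads meeting at a
trivalent node form a small triangle instead of a singular point.

Unit system throughout the particle model: nm, ns, zJ (1e-21 J) and 1e-21 kg
(which makes 1 zJ = 1 mass unit nm^2/ns^2); k_B = 0.01380649 zJ/K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hexgraph import Box, PeriodicGraph

__all__ = ["KB", "PotentialParams", "BeadSystem", "polymerize",
           "head_clusters", "write_lammps_data", "write_xyz"]

#: Boltzmann constant in zJ / K.
KB = 0.01380649

HEAD, BODY = 1, 0


@dataclass(frozen=True)
class PotentialParams:
    """All energy/length parameters of the particle model.

    Defaults: head-head LJ well 16.5 zJ (1200 K k_B), body-body repulsion
    64 zJ truncated at sigma_BB = 138 nm, cosine-squared angle stiffness
    200 zJ, shifted-Morse bonds with D_e = 16.5 zJ, alpha = 0.15 /nm,
    r_eqm = 50 nm, broken when longer than r_c = sigma_BB, Langevin
    thermostat at 100 K with a 1 ns damping time.

    sigma_HH defaults to 45 nm so that the head-head LJ minimum
    (2^(1/6) sigma_HH ~ 50.5 nm) matches the head-triplet spacing that the
    body-bead exclusion imposes at a trivalent node (three arms whose first
    body beads sit mutually at sigma_BB put the heads ~51 nm apart): the
    cross-link then binds with well depth ~eps_HH while the body repulsion
    supplies the junction's angular stiffness.  A much shorter range cannot
    reach across the junction and leaves the cross-links unbound.
    """

    eps_HH: float = 16.5          # zJ
    sigma_HH: float = 45.0        # nm
    eps_BB: float = 64.0          # zJ
    sigma_BB: float = 138.0       # nm
    K_theta: float = 200.0        # zJ
    D_e: float = 16.5             # zJ
    alpha: float = 0.150          # 1/nm
    r_eqm_bond: float = 50.0      # nm
    r_c: float = 138.0            # nm, bond-break cutoff
    temperature: float = 100.0    # K
    damping: float = 1.0          # ns
    mass: float = 0.1             # 1e-21 kg per bead
    hh_cutoff_factor: float = 2.5  # head LJ truncation, in units of sigma_HH

    def __post_init__(self) -> None:
        for name in ("eps_HH", "sigma_HH", "eps_BB", "sigma_BB", "D_e",
                     "alpha", "r_eqm_bond", "mass", "damping"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.K_theta < 0:
            raise ValueError("K_theta must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.r_c < self.sigma_BB:
            raise ValueError("r_c must be >= sigma_BB (the truncated repulsion "
                             "vanishes at sigma_BB, so equality is safe)")

    @property
    def hh_cutoff(self) -> float:
        return self.hh_cutoff_factor * self.sigma_HH

    @property
    def head_cluster_cutoff(self) -> float:
        """Default single-linkage cutoff for head clustering.

        Twice the head-head LJ minimum distance: wide enough to keep the
        freshly placed (not yet bound) head triplet of one node in a single
        cluster, narrow enough never to bridge distinct nodes ~300 nm apart.
        """
        return 2.0 * 2.0 ** (1.0 / 6.0) * self.sigma_HH

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class BeadSystem:
    """Mutable state of the particle simulation.

    Bond/angle arrays are allocated once at polymerisation; breaking marks
    entries dead in ``bond_alive``/``angle_alive`` rather than reallocating.
    ``molecule_id`` is the *current* connected component of each bead over
    alive bonds (nonbonded interactions are excluded within a molecule and
    re-enabled the moment it splits); ``source_molecule`` is the immutable
    graph edge index a bead came from.
    """

    positions: np.ndarray          # (N, 2) nm, unwrapped
    velocities: np.ndarray         # (N, 2) nm/ns
    bead_type: np.ndarray          # (N,) HEAD or BODY
    molecule_id: np.ndarray        # (N,)
    source_molecule: np.ndarray    # (N,) original edge index
    masses: np.ndarray             # (N,) 1e-21 kg
    bonds: np.ndarray              # (Nb, 2) bead indices
    bond_alive: np.ndarray         # (Nb,) bool
    angles: np.ndarray             # (Na, 3) bead indices i-j-k
    angle_bonds: np.ndarray        # (Na, 2) bond indices forming each angle
    angle_alive: np.ndarray        # (Na,) bool
    box: Box
    head_cluster_cutoff: float = 44.9
    source_edges: np.ndarray | None = None   # (E, 2) source-graph node ids

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_bonds_initial(self) -> int:
        return len(self.bonds)

    @property
    def n_bonds_alive(self) -> int:
        return int(np.count_nonzero(self.bond_alive))

    def head_indices(self) -> np.ndarray:
        return np.where(self.bead_type == HEAD)[0]

    def copy(self) -> "BeadSystem":
        return BeadSystem(self.positions.copy(), self.velocities.copy(),
                          self.bead_type.copy(), self.molecule_id.copy(),
                          self.source_molecule.copy(), self.masses.copy(),
                          self.bonds.copy(), self.bond_alive.copy(),
                          self.angles.copy(), self.angle_bonds.copy(),
                          self.angle_alive.copy(), self.box,
                          self.head_cluster_cutoff,
                          None if self.source_edges is None else self.source_edges.copy())

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention along periodic axes."""
        d = np.array(d, dtype=float, copy=True)
        for ax in range(2):
            if self.box.periodic[ax]:
                L = self.box.lengths[ax]
                d[..., ax] -= L * np.rint(d[..., ax] / L)
        return d

    def bond_lengths(self) -> np.ndarray:
        d = self.min_image(self.positions[self.bonds[:, 1]]
                           - self.positions[self.bonds[:, 0]])
        return np.linalg.norm(d, axis=1)


def polymerize(g: PeriodicGraph, params: PotentialParams | None = None,
               node_spacing: float = 300.0, graph_unit: float = 1.0) -> BeadSystem:
    """Build one six-bead polymer per graph edge.

    Graph coordinates are scaled by ``node_spacing / graph_unit`` (graph
    units of one edge length become the physical molecule length).  Beads
    are spaced exactly ``r_eqm_bond`` apart along each edge, centred on it;
    edges shorter than ``4 * r_eqm_bond`` after scaling are rejected as
    over-compressed.
    """
    params = params or PotentialParams()
    if g.n_edges == 0:
        raise ValueError("cannot polymerize a graph with no edges")
    scale = node_spacing / graph_unit
    pos_nm = g.positions * scale
    E = g.n_edges
    r_b = params.r_eqm_bond

    vecs = g.edge_vectors() * scale
    lengths = np.linalg.norm(vecs, axis=1)
    if np.any(lengths < 4.0 * r_b):
        raise ValueError("edge shorter than 4 * r_eqm_bond after scaling; "
                         "input graph is over-compressed")

    N = 6 * E
    positions = np.empty((N, 2))
    bead_type = np.empty(N, dtype=np.int8)
    molecule_id = np.repeat(np.arange(E, dtype=np.int64), 6)
    iu = np.array([g.index_of(int(u)) for u in g.edges[:, 0]])
    for e in range(E):
        unit = vecs[e] / lengths[e]
        start = (lengths[e] - 5.0 * r_b) / 2.0
        offsets = start + r_b * np.arange(6)
        positions[6 * e:6 * e + 6] = pos_nm[iu[e]] + offsets[:, None] * unit
        bead_type[6 * e:6 * e + 6] = [HEAD, BODY, BODY, BODY, BODY, HEAD]

    bonds = np.empty((5 * E, 2), dtype=np.int64)
    angles = np.empty((4 * E, 3), dtype=np.int64)
    angle_bonds = np.empty((4 * E, 2), dtype=np.int64)
    for e in range(E):
        for i in range(5):
            bonds[5 * e + i] = (6 * e + i, 6 * e + i + 1)
        for i in range(4):
            angles[4 * e + i] = (6 * e + i, 6 * e + i + 1, 6 * e + i + 2)
            angle_bonds[4 * e + i] = (5 * e + i, 5 * e + i + 1)

    box = Box((g.box.lx * scale, g.box.ly * scale), g.box.periodic)
    return BeadSystem(
        positions=positions,
        velocities=np.zeros((N, 2)),
        bead_type=bead_type,
        molecule_id=molecule_id,
        source_molecule=molecule_id.copy(),
        masses=np.full(N, params.mass),
        bonds=bonds,
        bond_alive=np.ones(5 * E, dtype=bool),
        angles=angles,
        angle_bonds=angle_bonds,
        angle_alive=np.ones(4 * E, dtype=bool),
        box=box,
        head_cluster_cutoff=params.head_cluster_cutoff,
        source_edges=g.edges.copy(),
    )


def head_clusters(sys: BeadSystem, cutoff: float | None = None) -> list[np.ndarray]:
    """Single-linkage clusters of head beads at the given distance cutoff.

    On an undamaged system at the default cutoff this recovers the source
    graph exactly: one cluster per node, of size equal to the node's
    coordination.
    """
    if cutoff is None:
        cutoff = sys.head_cluster_cutoff
    heads = sys.head_indices()
    h = len(heads)
    parent = np.arange(h)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if cutoff > 0 and h > 1:
        pos = sys.positions[heads]
        for i in range(h - 1):
            d = sys.min_image(pos[i + 1:] - pos[i])
            close = np.where(np.einsum("ij,ij->i", d, d) < cutoff * cutoff)[0]
            for j in close:
                ri, rj = find(i), find(i + 1 + j)
                if ri != rj:
                    parent[rj] = ri
    roots = np.array([find(i) for i in range(h)])
    clusters = [heads[roots == r] for r in np.unique(roots)]
    return clusters


# -- exporters ---------------------------------------------------------


def write_lammps_data(sys: BeadSystem, path, title: str = "hexrupture network") -> None:
    """LAMMPS data file, atom_style full (charge 0, z = 0); alive topology only."""
    alive_bonds = np.where(sys.bond_alive)[0]
    alive_angles = np.where(sys.angle_alive)[0]
    with open(path, "w") as f:
        f.write(f"{title}\n\n")
        f.write(f"{sys.n_beads} atoms\n")
        f.write(f"{len(alive_bonds)} bonds\n")
        f.write(f"{len(alive_angles)} angles\n\n")
        f.write("2 atom types\n1 bond types\n1 angle types\n\n")
        f.write(f"0.0 {sys.box.lx:.10g} xlo xhi\n")
        f.write(f"0.0 {sys.box.ly:.10g} ylo yhi\n")
        f.write("-1.0 1.0 zlo zhi\n\n")
        f.write("Masses\n\n")
        f.write(f"1 {sys.masses[sys.bead_type == BODY][0] if np.any(sys.bead_type == BODY) else sys.masses[0]:.10g}\n")
        f.write(f"2 {sys.masses[sys.bead_type == HEAD][0] if np.any(sys.bead_type == HEAD) else sys.masses[0]:.10g}\n\n")
        f.write("Atoms # full\n\n")
        for i in range(sys.n_beads):
            t = 2 if sys.bead_type[i] == HEAD else 1
            x, y = sys.positions[i]
            f.write(f"{i + 1} {int(sys.molecule_id[i]) + 1} {t} 0 "
                    f"{x:.10g} {y:.10g} 0\n")
        f.write("\nBonds\n\n")
        for n, b in enumerate(alive_bonds, start=1):
            i, j = sys.bonds[b]
            f.write(f"{n} 1 {i + 1} {j + 1}\n")
        f.write("\nAngles\n\n")
        for n, a in enumerate(alive_angles, start=1):
            i, j, k = sys.angles[a]
            f.write(f"{n} 1 {i + 1} {j + 1} {k + 1}\n")


def write_xyz(sys: BeadSystem, path, append: bool = False, time: float = 0.0) -> None:
    """Extended-XYZ snapshot (species, position, molecule id)."""
    mode = "a" if append else "w"
    with open(path, mode) as f:
        f.write(f"{sys.n_beads}\n")
        f.write(f'Lattice="{sys.box.lx:.10g} 0 0 0 {sys.box.ly:.10g} 0 0 0 1" '
                f'Properties=species:S:1:pos:R:3:mol:I:1 Time={time:.10g}\n')
        for i in range(sys.n_beads):
            sp = "H" if sys.bead_type[i] == HEAD else "B"
            x, y = sys.positions[i]
            f.write(f"{sp} {x:.10g} {y:.10g} 0 {int(sys.molecule_id[i])}\n")
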