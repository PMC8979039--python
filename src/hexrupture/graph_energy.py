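"""Graph-level elastic energy and local geometry optimisation.

The abstract network is given a cheap elastic energy so that defect
operations can relax node positions before the graph is turned into
polymers: harmonic bonds

    U_bond = k_bond (r - r_eqm)^2

and a cosine angle term between adjacent neighbour bearings around each node

    U_angle = K_angle (cos(theta) - cos(theta_eqm))^2,  theta_eqm = 2 pi / k,

where k is the coordination of the central node (120 deg for a trivalent
node).  By default only the bond term is active during defect relaxation
(K_angle = 0), which is fast and sufficient to remove the local strain a
bond switch or hole leaves behind; the angle term is available for final
polishing.  Minimisation uses scipy's L-BFGS-B with the analytic gradient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .hexgraph import PeriodicGraph

__all__ = ["GraphPotential", "bond_energy", "angle_energy",
           "total_energy", "gradient", "relax", "RelaxResult"]


@dataclass(frozen=True)
class GraphPotential:
    """Parameters of the graph-level energy (graph units)."""

    k_bond: float = 1.0
    K_angle: float = 0.0
    r_eqm: float = 1.0

    def __post_init__(self) -> None:
        if self.k_bond <= 0:
            raise ValueError("k_bond must be positive")
        if self.K_angle < 0:
            raise ValueError("K_angle must be non-negative")

    @staticmethod
    def theta_eqm(k: int) -> float:
        """Equilibrium angle 2 pi / k for a node of coordination k."""
        return 2.0 * math.pi / k


def bond_energy(r: float, pot: GraphPotential = GraphPotential()) -> float:
    """Harmonic bond energy k_bond (r - r_eqm)^2."""
    return pot.k_bond * (r - pot.r_eqm) ** 2


def angle_energy(theta: float, k: int, pot: GraphPotential = GraphPotential(K_angle=1.0)) -> float:
    """Angle energy K_angle (cos(theta) - cos(2 pi / k))^2."""
    return pot.K_angle * (math.cos(theta) - math.cos(GraphPotential.theta_eqm(k))) ** 2


def _angle_triplets(g: PeriodicGraph):
    """(centre idx, edge idx a, dir a, edge idx b, dir b, cos(theta_eqm)).

    Adjacent neighbour pairs in the angular (bearing) ordering around each
    node: k cyclic terms for coordination k >= 3, one term for k = 2.
    dir is +1 if the edge vector points away from the centre.
    """
    vecs = g.edge_vectors()
    triplets = []
    adj = g.adjacency()
    for n, incident in adj.items():
        k = len(incident)
        if k < 2:
            continue
        ci = g.index_of(n)
        # outgoing bearing of each incident edge
        items = []
        for _, e, d in incident:
            v = vecs[e] * d
            items.append((math.atan2(v[1], v[0]), e, d))
        items.sort()
        cos_eq = math.cos(GraphPotential.theta_eqm(k))
        pairs = range(k) if k >= 3 else range(1)
        for i in pairs:
            _, ea, da = items[i]
            _, eb, db = items[(i + 1) % k]
            triplets.append((ci, ea, da, eb, db, cos_eq))
    return triplets


def _energy_grad(flat_pos, g: PeriodicGraph, pot: GraphPotential, triplets,
                 iu, iv, want_grad=True):
    pos = flat_pos.reshape(-1, 2)
    L = np.asarray(g.box.lengths)
    vecs = pos[iv] + g.shifts * L - pos[iu]
    r = np.linalg.norm(vecs, axis=1)
    if np.any(r == 0):
        raise ValueError("coincident bonded nodes: gradient undefined")
    energy = float(np.sum(pot.k_bond * (r - pot.r_eqm) ** 2))
    grad = np.zeros_like(pos)
    if want_grad:
        # dU/dr = 2 k (r - r0); force along the unit edge vector
        coef = (2.0 * pot.k_bond * (r - pot.r_eqm) / r)[:, None] * vecs
        np.add.at(grad, iv, coef)
        np.add.at(grad, iu, -coef)
    if pot.K_angle > 0.0 and triplets:
        for ci, ea, da, eb, db, cos_eq in triplets:
            va = vecs[ea] * da
            vb = vecs[eb] * db
            ra = math.hypot(va[0], va[1])
            rb = math.hypot(vb[0], vb[1])
            ct = float(va @ vb) / (ra * rb)
            ct = max(-1.0, min(1.0, ct))
            energy += pot.K_angle * (ct - cos_eq) ** 2
            if want_grad:
                pref = 2.0 * pot.K_angle * (ct - cos_eq)
                dct_dva = vb / (ra * rb) - ct * va / (ra * ra)
                dct_dvb = va / (ra * rb) - ct * vb / (rb * rb)
                # va depends on positions: va = da * (pos[head]-pos[tail]...)
                ga = pref * dct_dva * da
                gb = pref * dct_dvb * db
                ia_u, ia_v = iu[ea], iv[ea]
                ib_u, ib_v = iu[eb], iv[eb]
                grad[ia_v] += ga
                grad[ia_u] -= ga
                grad[ib_v] += gb
                grad[ib_u] -= gb
    return energy, grad.ravel()


def _edge_endpoint_indices(g: PeriodicGraph):
    iu = np.array([g.index_of(int(u)) for u in g.edges[:, 0]], dtype=np.int64)
    iv = np.array([g.index_of(int(v)) for v in g.edges[:, 1]], dtype=np.int64)
    return iu, iv


def total_energy(g: PeriodicGraph, pot: GraphPotential = GraphPotential()) -> float:
    """Sum of bond terms over edges plus angle terms around every node."""
    if g.n_edges == 0:
        return 0.0
    iu, iv = _edge_endpoint_indices(g)
    triplets = _angle_triplets(g) if pot.K_angle > 0 else []
    e, _ = _energy_grad(g.positions.ravel(), g, pot, triplets, iu, iv, want_grad=False)
    return e


def gradient(g: PeriodicGraph, pot: GraphPotential = GraphPotential()) -> np.ndarray:
    """Analytic dU/dposition, shape (n_nodes, 2)."""
    if g.n_edges == 0:
        return np.zeros_like(g.positions)
    iu, iv = _edge_endpoint_indices(g)
    triplets = _angle_triplets(g) if pot.K_angle > 0 else []
    _, grad = _energy_grad(g.positions.ravel(), g, pot, triplets, iu, iv)
    return grad.reshape(-1, 2)


@dataclass
class RelaxResult:
    graph: PeriodicGraph
    energy: float
    converged: bool
    n_iterations: int


def relax(g: PeriodicGraph, pot: GraphPotential = GraphPotential(),
          frozen=(), tol: float = 1e-6, maxiter: int = 2000) -> RelaxResult:
    """Minimise node positions; ``frozen`` node ids are held fixed.

    Converged means the gradient max-norm over free coordinates is <= tol.
    On non-convergence the best-found positions are returned with a warning.
    """
    if g.n_edges == 0 or g.n_nodes == 0:
        return RelaxResult(g.copy(), 0.0, True, 0)
    iu, iv = _edge_endpoint_indices(g)
    triplets = _angle_triplets(g) if pot.K_angle > 0 else []
    frozen_idx = np.array(sorted(g.index_of(int(n)) for n in frozen), dtype=np.int64)
    free = np.ones(g.n_nodes, dtype=bool)
    if len(frozen_idx):
        free[frozen_idx] = False
    free_rows = np.where(free)[0]
    if len(free_rows) == 0:
        return RelaxResult(g.copy(), total_energy(g, pot), True, 0)

    base = g.positions.copy()

    def fun(x):
        pos = base.copy()
        pos[free_rows] = x.reshape(-1, 2)
        e, grad = _energy_grad(pos.ravel(), g, pot, triplets, iu, iv)
        return e, grad.reshape(-1, 2)[free_rows].ravel()

    res = minimize(fun, base[free_rows].ravel(), jac=True, method="L-BFGS-B",
                   options={"gtol": tol, "ftol": 1e-14, "maxiter": maxiter})
    pos = base.copy()
    pos[free_rows] = res.x.reshape(-1, 2)
    grad_inf = float(np.max(np.abs(res.jac))) if np.size(res.jac) else 0.0
    converged = grad_inf <= tol * (1.0 + 1e-9) or res.success
    if not converged:
        warnings.warn(f"graph relaxation did not converge (|grad|_inf = {grad_inf:.2e})",
                      RuntimeWarning, stacklevel=2)
    return RelaxResult(g.with_positions(pos), float(res.fun), bool(converged),
                       int(res.nit))
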