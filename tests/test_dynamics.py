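"""Integrator, thermostat, deformation schedules and bond breaking."""

import math

import numpy as np
import pytest

from hexrupture import dynamics as dy
from hexrupture import hexgraph as hg
from hexrupture import metrics as mt
from hexrupture import polymerize as pz


# -- schedules ---------------------------------------------------------


def test_linear_schedule_interpolates():
    s = dy.DeformationSchedule.linear(lambda_end=2.0, duration=10_000.0)
    assert s.factor(0.0) == 1.0
    assert s.factor(5_000.0) == pytest.approx(1.5)
    assert s.factor(10_000.0) == 2.0


def test_sinusoid_schedule_endpoints():
    w = 2 * math.pi / 1000.0
    s = dy.DeformationSchedule.sinusoid(amplitude=0.3, omega=w, duration=2000.0)
    assert s.factor(0.0) == 1.0
    assert s.factor(250.0) == pytest.approx(1.3)        # omega t = pi/2
    assert s.factor(750.0) == pytest.approx(0.7)


def test_schedule_validation():
    with pytest.raises(ValueError, match="fraction"):
        dy.DeformationSchedule.sinusoid(amplitude=1.5, omega=1.0, duration=10.0)
    with pytest.raises(ValueError):
        dy.DeformationSchedule.linear(lambda_end=2.0, duration=-1.0)
    with pytest.raises(ValueError):
        dy.DeformationSchedule.from_dict({"mode": "linear", "bogus": 1})


def test_timestep_stability_bound(minimized_2x2, default_params):
    assert dy.stability_max_dt(default_params) > 0.02
    with pytest.raises(ValueError, match="stability"):
        dy.run(minimized_2x2, default_params, dy.DeformationSchedule.none(),
               total_time=1.0, dt=1.0, seed=0)


# -- integration basics ------------------------------------------------


def test_minimized_system_is_static_at_zero_temperature(lattice_2x2,
                                                        default_params):
    """An isolated molecule at its minimum is exactly stationary; the full
    network is static to within the residual of its junctions, which sit on
    the truncation boundary of the body-bead repulsion."""
    p = default_params
    g = hg.PeriodicGraph(np.array([0, 1]), np.array([[0.0, 0.0], [1.0, 0.0]]),
                         np.array([[0, 1]]), np.zeros((1, 2), dtype=int),
                         hg.Box((10.0, 10.0), (False, False)))
    mol = pz.polymerize(g, p)          # bonds at r_eqm, angles straight
    assert np.abs(dy.forces(mol, p)).max() < 1e-9
    out, _ = dy.run(mol, p, dy.DeformationSchedule.none(), total_time=2.0,
                    dt=0.02, seed=0, thermostat=False, record_frames=False,
                    init_velocities=False)
    assert np.abs(out.positions - mol.positions).max() < 1e-9

    sys = pz.polymerize(lattice_2x2, p)
    sys = dy.minimize_system(sys, p, gtol=1e-6, maxiter=20_000)
    out, _ = dy.run(sys, p, dy.DeformationSchedule.none(), total_time=2.0,
                    dt=0.02, seed=0, thermostat=False, record_frames=False,
                    init_velocities=False)
    assert np.abs(out.positions - sys.positions).max() < 1.0


def test_box_follows_schedule_exactly(minimized_2x2, default_params):
    sched = dy.DeformationSchedule.linear(lambda_end=1.2, duration=100.0)
    out, traj = dy.run(minimized_2x2, default_params, sched, total_time=100.0,
                       dt=0.02, seed=1, sample_every=25.0, record_frames=False)
    lx0 = minimized_2x2.box.lx
    assert traj.box_lx[0] == pytest.approx(lx0)
    for t, lx in zip(traj.times, traj.box_lx):
        assert lx == pytest.approx(lx0 * sched.factor(t), rel=1e-12)
    assert out.box.lx == pytest.approx(1.2 * lx0, rel=1e-12)


def test_thermostat_reaches_equipartition(minimized_2x2, default_params):
    """Time-averaged kinetic energy per bead is k_B T (2 DOF) within 5%."""
    p = default_params
    o, _ = dy.run(minimized_2x2, p, dy.DeformationSchedule.none(),
                  total_time=200.0, dt=0.02, seed=5, record_frames=False)
    kes = []
    for i in range(30):   # 30 x 60 ns = 90k steps of production sampling
        o, _ = dy.run(o, p, dy.DeformationSchedule.none(), total_time=60.0,
                      dt=0.02, seed=100 + i, record_frames=False,
                      init_velocities=False)
        kes.append(dy.kinetic_energy(o) / o.n_beads)
    assert np.mean(kes) == pytest.approx(pz.KB * p.temperature, rel=0.05)


def test_energy_conservation_without_thermostat(default_params):
    """Velocity-Verlet NVE drift < 1e-3 relative over 1e4 steps.

    Uses a single molecule (bonds + angles; intramolecular pairs are
    excluded) so no bead sits on a nonbonded truncation boundary.
    """
    p = default_params
    g = hg.generate_hexagonal(2, 2)
    full = pz.polymerize(g, p)
    keep = np.arange(6)
    sub = pz.BeadSystem(
        full.positions[keep].copy(), np.zeros((6, 2)), full.bead_type[keep],
        full.molecule_id[keep], full.source_molecule[keep], full.masses[keep],
        full.bonds[:5].copy(), np.ones(5, dtype=bool), full.angles[:4].copy(),
        full.angle_bonds[:4].copy(), np.ones(4, dtype=bool), full.box,
        full.head_cluster_cutoff)
    rng = np.random.default_rng(0)
    sub.velocities = rng.normal(0, math.sqrt(pz.KB * 100 / p.mass), (6, 2))
    e0 = dy.potential_energy(sub, p) + dy.kinetic_energy(sub)
    out, _ = dy.run(sub, p, dy.DeformationSchedule.none(), total_time=200.0,
                    dt=0.02, seed=1, thermostat=False, record_frames=False,
                    init_velocities=False)
    e1 = dy.potential_energy(out, p) + dy.kinetic_energy(out)
    assert abs(e1 - e0) / abs(e0) < 1e-3


def test_free_bead_diffusion_matches_einstein_relation(default_params):
    """MSD slope of non-interacting thermostatted beads is 4 D = 4 k_B T tau/m."""
    p = default_params
    n = 200
    rng = np.random.default_rng(7)
    sys = pz.BeadSystem(
        positions=rng.uniform(0, 5000.0, (n, 2)),
        velocities=np.zeros((n, 2)),
        bead_type=np.full(n, pz.BODY, dtype=np.int8),
        molecule_id=np.zeros(n, dtype=np.int64),   # one molecule: no pairs
        source_molecule=np.zeros(n, dtype=np.int64),
        masses=np.full(n, p.mass),
        bonds=np.zeros((0, 2), dtype=np.int64), bond_alive=np.zeros(0, bool),
        angles=np.zeros((0, 3), dtype=np.int64),
        angle_bonds=np.zeros((0, 2), dtype=np.int64),
        angle_alive=np.zeros(0, bool),
        box=hg.Box((5000.0, 5000.0), (True, True)))
    total = 400.0
    _, traj = dy.run(sys, p, dy.DeformationSchedule.none(), total_time=total,
                     dt=0.02, seed=3, sample_every=10.0, record_frames=False)
    # late-time fit avoids the ballistic transient (tau = 1 ns)
    late = traj.times > 50.0
    slope = np.polyfit(traj.times[late], traj.msd[late], 1)[0]
    d_expected = pz.KB * p.temperature * p.damping / p.mass
    assert slope == pytest.approx(4 * d_expected, rel=0.15)


# -- bond breaking -----------------------------------------------------


@pytest.fixture()
def two_molecules(default_params):
    g = hg.PeriodicGraph(np.arange(3),
                         np.array([[100.0, 100.0], [400.0, 100.0],
                                   [400.0, 400.0]]) / 300.0,
                         np.array([[0, 1], [1, 2]]),
                         np.zeros((2, 2), dtype=int),
                         hg.Box((2000.0 / 300, 2000.0 / 300), (False, False)))
    return pz.polymerize(g, default_params)


def test_no_breaks_below_cutoff(two_molecules, default_params):
    assert dy.check_bond_breaks(two_molecules, default_params) == []
    assert np.all(two_molecules.bond_alive)


def test_single_overstretched_bond_breaks(two_molecules, default_params):
    sys = two_molecules
    b = 2                       # mid-chain bond of molecule 0
    i, j = sys.bonds[b]
    d = sys.positions[j] - sys.positions[i]
    sys.positions[j:6] += d / np.linalg.norm(d) * default_params.r_c
    events = dy.check_bond_breaks(sys, default_params, time=3.5)
    assert len(events) == 1
    ev = events[0]
    assert ev.bond_index == b and ev.time == 3.5
    assert not sys.bond_alive[b]
    # the two angles containing the broken bond are gone
    assert np.count_nonzero(sys.angle_alive) == 8 - 2
    # the molecule split into two fragments with distinct ids
    assert sys.molecule_id[int(i)] != sys.molecule_id[int(j)]
    # broken bonds stay broken
    assert dy.check_bond_breaks(sys, default_params) == []


def test_fragments_interact_after_split(two_molecules, default_params):
    """Nonbonded exclusion lapses once a molecule splits."""
    p = default_params
    sys = two_molecules
    u_before = dy.potential_energy(sys, p)
    b = 2
    sys.bond_alive[b] = False
    dead = ~sys.bond_alive[sys.angle_bonds]
    sys.angle_alive = sys.angle_alive & ~np.any(dead, axis=1)
    from hexrupture.dynamics import _refresh_molecules

    _refresh_molecules(sys)
    u_after = dy.potential_energy(sys, p)
    # fragment beads within sigma_BB now repel: energy strictly higher than
    # just removing the bond's (-D_e ish) and angle terms would explain
    removed = dy.morse_energy(50.0, p)
    assert u_after > u_before - removed


def test_n_broken_is_monotone_under_deformation(minimized_2x2, default_params):
    p = pz.PotentialParams(eps_HH=32.0, D_e=32.0)
    sched = dy.DeformationSchedule.sinusoid(0.45, 0.012, 600.0)
    _, traj = dy.run(minimized_2x2, p, sched, total_time=600.0, dt=0.02,
                     seed=11, record_frames=False)
    assert traj.n_broken[-1] > 0          # damage actually occurred
    assert np.all(np.diff(traj.n_broken) >= 0)
    # break events only accumulate
    times = [e.time for e in traj.events]
    assert times == sorted(times)


def test_step_returns_new_system(minimized_2x2, default_params):
    out = dy.step(minimized_2x2, default_params, dt=0.02, seed=0)
    assert out is not minimized_2x2
    assert out.positions.shape == minimized_2x2.positions.shape
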