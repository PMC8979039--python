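"""Damage metrics: broken fractions, effective graphs, polygons, MSD, onset."""

import math

import numpy as np
import pytest

from hexrupture import defects as df
from hexrupture import hexgraph as hg
from hexrupture import metrics as mt
from hexrupture import polymerize as pz

from conftest import hexagon_ring


def _traj(times, n_broken, mean_k=None):
    """Minimal trajectory for aggregation tests."""
    t = mt.DamageTrajectory(times=np.asarray(times, dtype=float),
                            n_broken=np.asarray(n_broken, dtype=float),
                            box_lx=np.zeros(len(times)),
                            msd=np.zeros(len(times)), events=[],
                            initial_system=None, frames=None)
    if mean_k is not None:
        t._mean_k_cache = np.asarray(mean_k, dtype=float)
    return t


# -- fraction broken ---------------------------------------------------


def test_fraction_broken(default_params):
    g = hg.generate_hexagonal(5, 2)          # 60 edges -> 300 bonds
    sys = pz.polymerize(g, default_params)
    assert mt.fraction_broken(sys) == 0.0
    sys.bond_alive[[0, 7, 123]] = False
    assert mt.fraction_broken(sys) == pytest.approx(0.01)
    sys.bond_alive[:] = False
    assert mt.fraction_broken(sys) == 1.0


def test_fraction_broken_requires_bonds():
    with pytest.raises(ValueError):
        sys = pz.BeadSystem(np.zeros((1, 2)), np.zeros((1, 2)),
                            np.array([pz.BODY], dtype=np.int8),
                            np.zeros(1, dtype=int), np.zeros(1, dtype=int),
                            np.ones(1), np.zeros((0, 2), dtype=int),
                            np.zeros(0, bool), np.zeros((0, 3), dtype=int),
                            np.zeros((0, 2), dtype=int), np.zeros(0, bool),
                            hg.Box((10.0, 10.0)))
        mt.fraction_broken(sys)


# -- effective coordination --------------------------------------------


def test_coordination_of_undamaged_lattice(lattice_2x2, default_params):
    sys = pz.polymerize(lattice_2x2, default_params)
    assert mt.network_coordination(sys) == pytest.approx(3.0)


def test_coordination_of_fully_separated_molecules(default_params):
    """Intact but detached molecules are isolated edges: <k> = 1."""
    sys = pz.polymerize(hexagon_ring(60.0), default_params)
    for m in range(6):       # scatter the molecules far apart
        sys.positions[6 * m:6 * m + 6] += np.array([2500.0 * m, 1800.0 * m])
    assert mt.network_coordination(sys) == pytest.approx(1.0)


def test_coordination_after_single_mid_bond_break(lattice_2x2, default_params):
    sys = pz.polymerize(lattice_2x2, default_params)
    sys.bond_alive[2] = False     # mid-chain bond of molecule 0
    V, E = lattice_2x2.n_nodes, lattice_2x2.n_edges
    assert mt.network_coordination(sys) == pytest.approx((2 * E - 2) / V)


# -- polygons ----------------------------------------------------------


def test_edges_per_polygon_ideal_is_six(lattice_3x3):
    assert mt.edges_per_polygon(lattice_3x3) == pytest.approx(6.0)
    assert mt.edges_per_polygon(hg.generate_hexagonal(5, 4)) == pytest.approx(6.0)


def test_edges_per_polygon_stone_wales_preserves_mean(lattice_4x4):
    g = df.bond_switch(lattice_4x4, seed=1)
    assert mt.edges_per_polygon(g) == pytest.approx(6.0)


def test_edges_per_polygon_rises_after_edge_removal(lattice_3x3):
    g = df.remove_random_edges(lattice_3x3, seed=0, n_edges=1)
    F = 18
    expected = (6 * (F - 2) + 10) / (F - 1)    # two hexagons -> one decagon
    assert mt.edges_per_polygon(g) == pytest.approx(expected)
    assert mt.edges_per_polygon(g) > 6.0


def test_edges_per_polygon_needs_faces():
    single = hg.PeriodicGraph(np.array([0, 1]), np.array([[1.0, 1], [2.0, 1]]),
                              np.zeros((0, 2), dtype=int),
                              np.zeros((0, 2), dtype=int),
                              hg.Box((5.0, 5.0), (False, False)))
    with pytest.raises(ValueError):
        mt.edges_per_polygon(single)


# -- first damage and MSD ----------------------------------------------


def test_time_to_first_damage():
    assert mt.time_to_first_damage(_traj([0, 1], [0, 0])) == math.inf
    t = _traj([0, 1], [0, 0])
    t.events = [mt.BreakEvent(5100.0, 0, (0, 1), 0, 0, (0, 0)),
                mt.BreakEvent(3200.0, 1, (2, 3), 1, 1, (0, 0))]
    assert mt.time_to_first_damage(t) == 3200.0


def test_msd_starts_at_zero_and_ignores_affine_motion(minimized_2x2,
                                                      default_params):
    from hexrupture import dynamics as dy

    sched = dy.DeformationSchedule.linear(lambda_end=1.5, duration=50.0)
    # non-interacting beads at T = 0 move purely affinely with the box:
    # the non-affine MSD is identically zero while the box grows by 50%
    n = 16
    rng = np.random.default_rng(1)
    free = pz.BeadSystem(
        positions=rng.uniform(0, 1800.0, (n, 2)),
        velocities=np.zeros((n, 2)),
        bead_type=np.full(n, pz.BODY, dtype=np.int8),
        molecule_id=np.zeros(n, dtype=np.int64),
        source_molecule=np.zeros(n, dtype=np.int64),
        masses=np.full(n, default_params.mass),
        bonds=np.zeros((0, 2), dtype=np.int64), bond_alive=np.zeros(0, bool),
        angles=np.zeros((0, 3), dtype=np.int64),
        angle_bonds=np.zeros((0, 2), dtype=np.int64),
        angle_alive=np.zeros(0, bool),
        box=hg.Box((1800.0, 1039.2), (True, True)))
    _, traj = dy.run(free, default_params, sched, total_time=50.0,
                     dt=0.02, seed=0, thermostat=False, record_frames=False,
                     init_velocities=False)
    assert traj.msd[0] == 0.0
    assert np.allclose(mt.msd(traj), 0.0, atol=1e-16)


# -- break location classification -------------------------------------


def test_classify_break_location(default_params):
    g0 = hg.generate_hexagonal(4, 4)
    boundary = df.hole_boundary_nodes(g0, 0, 1)
    g = df.cut_hole(g0, 0, 1, relax=False)
    sys = pz.polymerize(g, default_params)

    def event_for_edge(e):
        return mt.BreakEvent(1.0, 5 * e + 2, (6 * e + 2, 6 * e + 3), e, e, (0, 0))

    rim_edge = next(i for i, (u, v) in enumerate(g.edges)
                    if int(u) in boundary or int(v) in boundary)
    assert mt.classify_break_location(event_for_edge(rim_edge), sys, g,
                                      boundary, 1) == "edge"
    # a sufficiently large cutoff labels everything "edge"
    for e in range(0, g.n_edges, 7):
        assert mt.classify_break_location(event_for_edge(e), sys, g,
                                          boundary, 10 ** 6) == "edge"
    with pytest.raises(ValueError):
        mt.classify_break_location(event_for_edge(0), sys, g, set(), 1)


def test_classify_far_edge_is_bulk(default_params):
    g0 = hg.generate_hexagonal(6, 6)
    center = 0
    boundary = df.hole_boundary_nodes(g0, center, 1)
    g = df.cut_hole(g0, center, 1, relax=False)
    sys = pz.polymerize(g, default_params)
    # farthest edge by breadth-first distance from the rim
    import networkx as nx

    gx = g.to_networkx()
    dist = nx.multi_source_dijkstra_path_length(gx, set(boundary) & set(gx))
    far_edge = max(range(g.n_edges),
                   key=lambda i: dist[int(g.edges[i][0])] + dist[int(g.edges[i][1])])
    ev = mt.BreakEvent(1.0, 5 * far_edge, (0, 1), far_edge, far_edge, (0, 0))
    assert mt.classify_break_location(ev, sys, g, boundary, 1) == "bulk"


# -- aggregation -------------------------------------------------------


def test_aggregate_identical_trajectories():
    t = [_traj([0, 1, 2], [0.0, 0.1, 0.2]) for _ in range(3)]
    out = mt.aggregate(t, n_points=3)
    assert np.allclose(out["n_broken_std"], 0.0)
    assert np.allclose(out["n_broken_mean"], [0.0, 0.1, 0.2])


def test_aggregate_population_convention():
    out = mt.aggregate([_traj([0, 1], [0.0, 0.1]),
                        _traj([0, 1], [0.0, 0.3])], n_points=2)
    assert out["n_broken_mean"].iloc[-1] == pytest.approx(0.2)
    assert out["n_broken_std"].iloc[-1] == pytest.approx(0.1)   # ddof = 0


def test_aggregate_mean_stabilises_with_more_repeats():
    """Standard error of the aggregated mean shrinks like 1/sqrt(n)."""
    rng = np.random.default_rng(0)

    def spread(n_repeats, n_groups=40):
        means = []
        for _ in range(n_groups):
            trajs = [_traj([0.0, 1.0], [0.0, 0.2 + rng.normal(0, 0.05)])
                     for _ in range(n_repeats)]
            means.append(mt.aggregate(trajs, n_points=2)["n_broken_mean"].iloc[-1])
        return np.std(means)

    ratio = spread(4) / spread(16)
    assert 1.4 < ratio < 3.0          # ideally 2 = sqrt(16/4)


def test_aggregate_requires_two():
    with pytest.raises(ValueError):
        mt.aggregate([_traj([0, 1], [0, 0])])


# -- rupture onset -----------------------------------------------------


def test_onset_detects_cascade_after_quiet_start():
    quiet = [1000.0, 1600.0]
    burst = [3000.0 + 10.0 * i for i in range(20)]
    times = quiet + burst
    onset = mt.rupture_onset(times)
    assert onset == 3000.0
    # the detector's own guarantee: forward rate > 5x preceding rate
    i = times.index(onset)
    ahead = sum(1 for t in times if onset <= t < onset + 500.0)
    assert ahead / 500.0 > 5 * (i / onset)


def test_onset_edge_cases():
    assert mt.rupture_onset([]) == math.inf
    assert mt.rupture_onset([123.0]) == 123.0          # fallback: lone event
    # uniform slow drip never accelerates: falls back to max-rate time
    drip = list(np.arange(1, 20) * 1000.0)
    assert mt.rupture_onset(drip) in drip
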