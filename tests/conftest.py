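import numpy as np
import pytest
from hypothesis import settings

from hexrupture import dynamics, hexgraph, polymerize

settings.register_profile("ci", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lattice_2x2():
    return hexgraph.generate_hexagonal(2, 2)


@pytest.fixture(scope="session")
def lattice_3x3():
    return hexgraph.generate_hexagonal(3, 3)


@pytest.fixture(scope="session")
def lattice_4x4():
    return hexgraph.generate_hexagonal(4, 4)


@pytest.fixture(scope="session")
def default_params():
    return polymerize.PotentialParams()


@pytest.fixture(scope="session")
def minimized_2x2(lattice_2x2, default_params):
    """A small relaxed bead system shared by dynamics tests (read-only)."""
    sys = polymerize.polymerize(lattice_2x2, default_params)
    return dynamics.minimize_system(sys, default_params)


@pytest.fixture(scope="session")
def rupture_study():
    """The linear-stretch-to-rupture study (the expensive shared fixture)."""
    from hexrupture.experiments import linear_rupture_study

    return linear_rupture_study(seed=20260926, n_seeds=8)


def hexagon_ring(radius_box: float = 10.0) -> hexgraph.PeriodicGraph:
    """A single non-periodic hexagon (6-cycle) helper."""
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    pos = np.c_[np.cos(ang), np.sin(ang)]
    pos = pos - pos.min(axis=0) + 1.0
    edges = np.array([(i, (i + 1) % 6) for i in range(6)])
    return hexgraph.PeriodicGraph(
        np.arange(6), pos, edges, np.zeros((6, 2), dtype=int),
        hexgraph.Box((radius_box, radius_box), (False, False)))
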