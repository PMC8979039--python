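"""2D Langevin dynamics with breakable Morse bonds and imposed box strain.

The particle model follows the coarse-grained network description: bonded
beads interact through a shifted Morse potential (cut, never re-formed, when
a bond exceeds r_c), intramolecular triplets through a cosine-squared angle
term, body beads of *different* molecules repel through a Lennard-Jones
potential truncated at its zero crossing sigma_BB, and head beads of
different molecules attract through a truncated-shifted Lennard-Jones well
(the repairable cross-links).  All intramolecular nonbonded pairs are
excluded; the exclusion lapses the moment a molecule splits.

Integration is BAOAB Langevin (velocity Verlet when the thermostat is off)
confined to the plane, with the box length L_x following a
:class:`DeformationSchedule` and bead x-coordinates remapped affinely on
every box change.  Units: nm, ns, zJ, 1e-21 kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import minimize as _scipy_minimize
from scipy.sparse.csgraph import connected_components

from . import _kernels
from .hexgraph import Box
from .metrics import BreakEvent, DamageTrajectory
from .polymerize import KB, BeadSystem, PotentialParams

__all__ = [
    "DeformationSchedule",
    "morse_energy",
    "wca_repulsion",
    "head_attraction",
    "angle_cos2",
    "stability_max_dt",
    "potential_energy",
    "kinetic_energy",
    "check_bond_breaks",
    "step",
    "run",
    "minimize_system",
]


# -- deformation schedules ---------------------------------------------


@dataclass(frozen=True)
class DeformationSchedule:
    """Box-length schedule L_x(t) = L_x0 * factor(t).

    Modes: ``none``; ``linear`` (engineering strain at constant rate, the
    stretching ratio lambda running from ``lambda_start`` to ``lambda_end``
    over ``duration``); ``sinusoid`` (L_x = L_x0 (1 + A sin(omega t)), A the
    *fractional* amplitude, 0 <= A < 1); ``sinusoid_ramp`` (amplitude grows
    linearly from 0 to ``amplitude`` over ``duration``).
    """

    mode: str = "none"
    lambda_start: float = 1.0
    lambda_end: float = 2.0
    amplitude: float = 0.0
    omega: float = 0.0          # angular frequency, rad/ns
    duration: float = 0.0       # ns

    def __post_init__(self) -> None:
        if self.mode not in ("none", "linear", "sinusoid", "sinusoid_ramp"):
            raise ValueError(f"unknown deformation mode {self.mode!r}")
        if self.mode != "none":
            if self.duration <= 0:
                raise ValueError("duration must be positive")
        if self.mode == "linear":
            if self.lambda_start <= 0 or self.lambda_end <= 0:
                raise ValueError("stretching ratios must be positive")
        if self.mode in ("sinusoid", "sinusoid_ramp"):
            if not (0.0 <= self.amplitude < 1.0):
                raise ValueError(
                    "fractional amplitude must satisfy 0 <= A < 1 (a peak "
                    "stretch ratio 1+A is specified by its fractional part)")

    @classmethod
    def none(cls) -> "DeformationSchedule":
        return cls(mode="none")

    @classmethod
    def linear(cls, lambda_end: float, duration: float,
               lambda_start: float = 1.0) -> "DeformationSchedule":
        return cls(mode="linear", lambda_start=lambda_start,
                   lambda_end=lambda_end, duration=duration)

    @classmethod
    def sinusoid(cls, amplitude: float, omega: float,
                 duration: float) -> "DeformationSchedule":
        return cls(mode="sinusoid", amplitude=amplitude, omega=omega,
                   duration=duration)

    @classmethod
    def sinusoid_ramp(cls, amplitude: float, omega: float,
                      duration: float) -> "DeformationSchedule":
        return cls(mode="sinusoid_ramp", amplitude=amplitude, omega=omega,
                   duration=duration)

    def factor(self, t: float) -> float:
        """Stretching ratio lambda(t) = L_x(t) / L_x0."""
        if self.mode == "none":
            return 1.0
        if self.mode == "linear":
            frac = min(max(t, 0.0), self.duration) / self.duration
            return self.lambda_start + (self.lambda_end - self.lambda_start) * frac
        if self.mode == "sinusoid":
            return 1.0 + self.amplitude * math.sin(self.omega * t)
        # sinusoid_ramp
        a = self.amplitude * min(max(t, 0.0), self.duration) / self.duration
        return 1.0 + a * math.sin(self.omega * t)

    def factor_array(self, t: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`factor`."""
        t = np.asarray(t, dtype=float)
        if self.mode == "none":
            return np.ones_like(t)
        if self.mode == "linear":
            frac = np.clip(t, 0.0, self.duration) / self.duration
            return self.lambda_start + (self.lambda_end - self.lambda_start) * frac
        if self.mode == "sinusoid":
            return 1.0 + self.amplitude * np.sin(self.omega * t)
        a = self.amplitude * np.clip(t, 0.0, self.duration) / self.duration
        return 1.0 + a * np.sin(self.omega * t)

    def to_dict(self) -> dict:
        return {"mode": self.mode, "lambda_start": self.lambda_start,
                "lambda_end": self.lambda_end, "amplitude": self.amplitude,
                "omega": self.omega, "duration": self.duration}

    @classmethod
    def from_dict(cls, d: dict) -> "DeformationSchedule":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown schedule keys: {sorted(unknown)}")
        return cls(**d)


# -- individual potentials (reference forms, used by tests and docs) ---


def morse_energy(r, p: PotentialParams) -> float:
    """Shifted Morse bond: D_e (1 - exp(-alpha (r - r_eqm)))^2 - D_e."""
    ex = np.exp(-p.alpha * (np.asarray(r, dtype=float) - p.r_eqm_bond))
    return p.D_e * (1.0 - ex) ** 2 - p.D_e


def wca_repulsion(r, eps_BB: float, sigma_BB: float):
    """Body-body LJ 12-6 truncated at its zero crossing sigma_BB."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    s6 = (sigma_BB / r) ** 6
    u = 4.0 * eps_BB * (s6 * s6 - s6)
    return np.where(r < sigma_BB, u, 0.0)[()]


def head_attraction(r, eps_HH: float, sigma_HH: float, cutoff: float | None = None):
    """Head-head LJ 12-6, truncated and shifted to zero at the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if cutoff is None:
        cutoff = 2.5 * sigma_HH
    s6c = (sigma_HH / cutoff) ** 6
    shift = 4.0 * eps_HH * (s6c * s6c - s6c)
    s6 = (sigma_HH / r) ** 6
    u = 4.0 * eps_HH * (s6 * s6 - s6) - shift
    return np.where(r < cutoff, u, 0.0)[()]


def angle_cos2(theta, K_theta: float):
    """Cosine-squared bending: K cos^2(theta/2); zero for a straight triplet."""
    return K_theta * np.cos(np.asarray(theta, dtype=float) / 2.0) ** 2


def stability_max_dt(p: PotentialParams) -> float:
    """One fiftieth of the stiffest bond period, sqrt(m / (2 D_e alpha^2))."""
    k_max = 2.0 * p.D_e * p.alpha ** 2
    return (2.0 * math.pi / 50.0) * math.sqrt(p.mass / k_max)


# -- kernel plumbing ---------------------------------------------------


def _hh_shift(p: PotentialParams) -> float:
    s6c = (p.sigma_HH / p.hh_cutoff) ** 6
    return 4.0 * p.eps_HH * (s6c * s6c - s6c)


def _build_pairs(sys: BeadSystem, p: PotentialParams, skin: float):
    return _kernels.build_pairs_cells(
        sys.positions, sys.box.lx, sys.box.ly,
        sys.box.periodic[0], sys.box.periodic[1],
        sys.bead_type, p.sigma_BB + skin, p.hh_cutoff + skin)


def _forces(sys: BeadSystem, p: PotentialParams, pairs, frc: np.ndarray) -> float:
    pi, pj, pk = pairs
    return _kernels.forces_energy(
        sys.positions, frc, sys.box.lx, sys.box.ly,
        sys.box.periodic[0], sys.box.periodic[1],
        sys.bonds, sys.bond_alive, p.D_e, p.alpha, p.r_eqm_bond,
        sys.angles, sys.angle_alive, p.K_theta,
        pi, pj, pk, sys.molecule_id,
        p.eps_BB, p.sigma_BB, p.eps_HH, p.sigma_HH, p.hh_cutoff, _hh_shift(p))


def potential_energy(sys: BeadSystem, p: PotentialParams) -> float:
    """Total potential energy of the current configuration (zJ)."""
    pairs = _build_pairs(sys, p, 0.0)
    frc = np.zeros_like(sys.positions)
    return float(_forces(sys, p, pairs, frc))


def forces(sys: BeadSystem, p: PotentialParams) -> np.ndarray:
    """Forces on every bead (zJ/nm)."""
    pairs = _build_pairs(sys, p, 0.0)
    frc = np.zeros_like(sys.positions)
    _forces(sys, p, pairs, frc)
    return frc


def kinetic_energy(sys: BeadSystem) -> float:
    return float(0.5 * np.sum(sys.masses[:, None] * sys.velocities ** 2))


# -- bond breaking -----------------------------------------------------


def _refresh_molecules(sys: BeadSystem) -> None:
    """Relabel molecule ids as connected components over alive bonds."""
    alive = sys.bonds[sys.bond_alive]
    n = sys.n_beads
    if len(alive):
        m = sparse.coo_matrix((np.ones(len(alive)), (alive[:, 0], alive[:, 1])),
                              shape=(n, n))
        _, labels = connected_components(m, directed=False)
    else:
        labels = np.arange(n)
    sys.molecule_id = labels.astype(np.int64)


def check_bond_breaks(sys: BeadSystem, p: PotentialParams,
                      time: float = 0.0) -> list[BreakEvent]:
    """Delete every bond longer than r_c; update angles and molecule ids.

    Returns the list of break events (empty if nothing broke).  Broken bonds
    never re-form; the beads of a split molecule immediately interact as
    intermolecular pairs.
    """
    lengths = sys.bond_lengths()
    broken = np.where(sys.bond_alive & (lengths > p.r_c))[0]
    if len(broken) == 0:
        return []
    events = []
    for b in broken:
        i, j = (int(x) for x in sys.bonds[b])
        d = sys.min_image(sys.positions[j] - sys.positions[i])
        mid = sys.positions[i] + 0.5 * d
        events.append(BreakEvent(
            time=float(time), bond_index=int(b), beads=(i, j),
            molecule_id=int(sys.molecule_id[i]),
            source_molecule=int(sys.source_molecule[i]),
            position=(float(mid[0]), float(mid[1]))))
        sys.bond_alive[b] = False
    dead = ~sys.bond_alive[sys.angle_bonds]
    sys.angle_alive = sys.angle_alive & ~np.any(dead, axis=1)
    _refresh_molecules(sys)
    return events


# -- integration -------------------------------------------------------


def _init_velocities(sys: BeadSystem, p: PotentialParams,
                     rng: np.random.Generator) -> None:
    sigma = np.sqrt(KB * p.temperature / sys.masses)
    sys.velocities = rng.normal(0.0, 1.0, size=(sys.n_beads, 2)) * sigma[:, None]


def step(sys: BeadSystem, p: PotentialParams, dt: float = 0.02,
         seed=0, thermostat: bool = True) -> BeadSystem:
    """Advance a copy of the system one time step (convenience wrapper)."""
    out, _ = run(sys, p, DeformationSchedule.none(), total_time=dt, dt=dt,
                 seed=seed, thermostat=thermostat, record_frames=False,
                 init_velocities=False)
    return out


def run(sys: BeadSystem, p: PotentialParams, schedule: DeformationSchedule,
        total_time: float, dt: float | None = None, seed=0,
        sample_every: float | None = None, break_every: int = 10,
        thermostat: bool = True, record_frames: bool = True,
        init_velocities: bool = True) -> tuple[BeadSystem, DamageTrajectory]:
    """Deform and integrate; returns (final system, damage trajectory).

    ``sys`` is not modified.  ``break_every`` is the bond-break check cadence
    in steps.  When ``init_velocities`` and the stored velocities are all
    zero, Maxwell-Boltzmann velocities at the thermostat temperature are
    drawn first.  All randomness derives from ``seed``.
    """
    if dt is None:
        dt = min(0.02, stability_max_dt(p))
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > stability_max_dt(p) * (1 + 1e-12):
        raise ValueError(f"dt = {dt} exceeds the stability bound "
                         f"{stability_max_dt(p):.4g} ns")
    sys = sys.copy()
    ss = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence)
                                else seed.entropy)
    ss_vel, ss_noise = ss.spawn(2)
    rng = np.random.default_rng(ss_vel)
    # separate, cheaper bit stream for the thermostat noise
    noise_rng = np.random.Generator(np.random.SFC64(ss_noise))
    if init_velocities and thermostat and p.temperature > 0 \
            and not np.any(sys.velocities):
        _init_velocities(sys, p, rng)

    n_steps = max(1, int(round(total_time / dt)))
    if sample_every is None:
        sample_every = total_time / 200.0
    sample_stride = max(1, int(round(sample_every / dt)))

    lx0 = sys.box.lx
    ly = sys.box.ly
    perx, pery = sys.box.periodic
    skin = 0.3 * p.sigma_BB
    inv_mass = 1.0 / sys.masses
    c1 = math.exp(-dt / p.damping) if thermostat else 1.0
    sigma_v = np.sqrt(KB * p.temperature * (1.0 - c1 * c1) / sys.masses) \
        if thermostat else np.zeros(sys.n_beads)
    hh_shift = _hh_shift(p)

    pairs = _build_pairs(sys, p, skin)
    pos_at_build = sys.positions.copy()
    frc = np.zeros_like(sys.positions)
    _forces(sys, p, pairs, frc)

    pos0 = sys.positions.copy()
    events: list[BreakEvent] = []
    initial_bonds = max(sys.n_bonds_initial, 1)
    initial_system = sys.copy()

    times = [0.0]
    n_broken = [(initial_bonds - sys.n_bonds_alive) / initial_bonds
                if sys.n_bonds_initial else 0.0]
    box_lx = [lx0 * schedule.factor(0.0)]
    msd_series = [0.0]
    frames = [sys.positions.astype(np.float32)] if record_frames else None

    cur_lx = lx0 * schedule.factor(0.0)
    if cur_lx != lx0:
        sys.positions[:, 0] *= cur_lx / lx0
    done = 0
    next_sample = sample_stride
    noise_buf = np.empty((break_every, sys.n_beads, 2), dtype=np.float32)
    zero_noise = np.zeros((0, 0, 2), dtype=np.float32)
    while done < n_steps:
        chunk = min(break_every, n_steps - done)
        t_steps = (np.arange(done + 1, done + chunk + 1)) * dt
        lx_steps = lx0 * schedule.factor_array(t_steps)
        if np.any(lx_steps <= 0):
            raise ValueError("schedule drives the box length non-positive")
        if thermostat:
            noise = noise_buf[:chunk]
            noise_rng.standard_normal(out=noise, dtype=np.float32)
        else:
            noise = zero_noise
        _, cur_lx = _kernels.integrate_chunk(
            sys.positions, sys.velocities, frc, inv_mass, dt, lx_steps,
            cur_lx, ly, perx, pery,
            sys.bonds, sys.bond_alive, p.D_e, p.alpha, p.r_eqm_bond,
            sys.angles, sys.angle_alive, p.K_theta,
            pairs[0], pairs[1], pairs[2], sys.molecule_id,
            p.eps_BB, p.sigma_BB, p.eps_HH, p.sigma_HH, p.hh_cutoff, hh_shift,
            thermostat, c1, sigma_v, noise)
        done += chunk
        t_now = done * dt

        if _kernels.count_bonds_over(sys.positions, sys.bonds, sys.bond_alive,
                                     cur_lx, ly, perx, pery, p.r_c):
            sys.box = Box((cur_lx, ly), sys.box.periodic)
            events.extend(check_bond_breaks(sys, p, time=t_now))

        if _kernels.max_abs_displacement(sys.positions, pos_at_build) > 0.5 * skin:
            sys.box = Box((cur_lx, ly), sys.box.periodic)
            pairs = _build_pairs(sys, p, skin)
            pos_at_build = sys.positions.copy()
            _forces(sys, p, pairs, frc)

        if done >= next_sample or done == n_steps:
            next_sample = (done // sample_stride + 1) * sample_stride
            sys.box = Box((cur_lx, ly), sys.box.periodic)
            if not np.all(np.isfinite(sys.positions)):
                raise RuntimeError(f"non-finite coordinates at t = {t_now} ns")
            times.append(t_now)
            n_broken.append((initial_bonds - sys.n_bonds_alive) / initial_bonds
                            if sys.n_bonds_initial else 0.0)
            box_lx.append(cur_lx)
            na = sys.positions - pos0
            na[:, 0] = sys.positions[:, 0] - pos0[:, 0] * (cur_lx / lx0)
            msd_series.append(float(np.mean(np.sum(na * na, axis=1))))
            if record_frames:
                frames.append(sys.positions.astype(np.float32))

    traj = DamageTrajectory(
        times=np.array(times), n_broken=np.array(n_broken),
        box_lx=np.array(box_lx), msd=np.array(msd_series),
        events=events, initial_system=initial_system, frames=frames)
    return sys, traj


def minimize_system(sys: BeadSystem, p: PotentialParams,
                    gtol: float = 1e-3, maxiter: int = 5000) -> BeadSystem:
    """Relax bead positions to a local potential-energy minimum (L-BFGS)."""
    sys = sys.copy()
    skin = 1.0 * p.sigma_BB
    state = {"pairs": _build_pairs(sys, p, skin),
             "ref": sys.positions.copy()}
    frc = np.zeros_like(sys.positions)

    def fun(x):
        sys.positions = x.reshape(-1, 2)
        if _kernels.max_abs_displacement(sys.positions, state["ref"]) > 0.5 * skin:
            state["pairs"] = _build_pairs(sys, p, skin)
            state["ref"] = sys.positions.copy()
        u = _forces(sys, p, state["pairs"], frc)
        return u, -frc.ravel()

    res = _scipy_minimize(fun, sys.positions.ravel().copy(), jac=True,
                          method="L-BFGS-B",
                          options={"gtol": gtol, "ftol": 1e-12, "maxiter": maxiter})
    sys.positions = res.x.reshape(-1, 2)
    return sys
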