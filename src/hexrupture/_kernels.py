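"""Numba kernels for the particle dynamics inner loops.

All arrays are plain numpy; the kernels know nothing about the BeadSystem
wrapper.  Minimum-image is applied per axis where the box is periodic and
works for unwrapped coordinates of any magnitude.  Nonbonded pairs are
pre-filtered by bead type (body-body and head-head only) with a skin; the
same-molecule exclusion is checked live against the molecule-id array so
that bond breaking re-enables pair interactions without a list rebuild.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _min_image(dx, dy, lx, ly, perx, pery):
    if perx:
        dx -= lx * np.floor(dx / lx + 0.5)
    if pery:
        dy -= ly * np.floor(dy / ly + 0.5)
    return dx, dy


@njit(cache=True)
def build_pairs(pos, lx, ly, perx, pery, bead_type, cut_bb, cut_hh):
    """Brute-force neighbour list.  Returns (i, j, kind); kind 0=BB, 1=HH."""
    n = pos.shape[0]
    cut2_bb = cut_bb * cut_bb
    cut2_hh = cut_hh * cut_hh
    count = 0
    for i in range(n - 1):
        ti = bead_type[i]
        for j in range(i + 1, n):
            tj = bead_type[j]
            if ti != tj:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dx, dy = _min_image(dx, dy, lx, ly, perx, pery)
            r2 = dx * dx + dy * dy
            if ti == 0:
                if r2 < cut2_bb:
                    count += 1
            else:
                if r2 < cut2_hh:
                    count += 1
    pi = np.empty(count, dtype=np.int64)
    pj = np.empty(count, dtype=np.int64)
    pk = np.empty(count, dtype=np.int8)
    m = 0
    for i in range(n - 1):
        ti = bead_type[i]
        for j in range(i + 1, n):
            tj = bead_type[j]
            if ti != tj:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dx, dy = _min_image(dx, dy, lx, ly, perx, pery)
            r2 = dx * dx + dy * dy
            if (ti == 0 and r2 < cut2_bb) or (ti == 1 and r2 < cut2_hh):
                pi[m] = i
                pj[m] = j
                pk[m] = 0 if ti == 0 else 1
                m += 1
    return pi, pj, pk


@njit(cache=True)
def forces_energy(pos, frc, lx, ly, perx, pery,
                  bonds, bond_alive, d_e, alpha, r0,
                  angles, angle_alive, k_theta,
                  pi, pj, pk, mol,
                  eps_bb, sig_bb, eps_hh, sig_hh, cut_hh, shift_hh):
    """Fill ``frc`` with forces; return the potential energy.

    Bonds: shifted Morse U = D_e (1 - exp(-alpha (r - r0)))^2 - D_e.
    Angles: U = K_theta cos^2(theta / 2) = K_theta (1 + cos theta) / 2.
    BB pairs: LJ 12-6 truncated at its zero crossing sigma_BB.
    HH pairs: LJ 12-6 truncated and shifted at cut_hh.
    """
    n = pos.shape[0]
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
    u = 0.0

    for b in range(bonds.shape[0]):
        if not bond_alive[b]:
            continue
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dx, dy = _min_image(dx, dy, lx, ly, perx, pery)
        r = np.sqrt(dx * dx + dy * dy)
        ex = np.exp(-alpha * (r - r0))
        u += d_e * (1.0 - ex) * (1.0 - ex) - d_e
        # dU/dr = 2 D_e alpha ex (1 - ex)
        fmag = -2.0 * d_e * alpha * ex * (1.0 - ex) / r
        fx = fmag * dx
        fy = fmag * dy
        frc[j, 0] += fx
        frc[j, 1] += fy
        frc[i, 0] -= fx
        frc[i, 1] -= fy

    half_k = 0.5 * k_theta
    for a in range(angles.shape[0]):
        if not angle_alive[a]:
            continue
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        ax, ay = _min_image(ax, ay, lx, ly, perx, pery)
        bx, by = _min_image(bx, by, lx, ly, perx, pery)
        ra = np.sqrt(ax * ax + ay * ay)
        rb = np.sqrt(bx * bx + by * by)
        ct = (ax * bx + ay * by) / (ra * rb)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        u += half_k * (1.0 + ct)
        # dU/dcos(theta) = K/2; f = -dU/dpos
        dca_x = (bx / (ra * rb) - ct * ax / (ra * ra))
        dca_y = (by / (ra * rb) - ct * ay / (ra * ra))
        dcb_x = (ax / (ra * rb) - ct * bx / (rb * rb))
        dcb_y = (ay / (ra * rb) - ct * by / (rb * rb))
        fi_x = -half_k * dca_x
        fi_y = -half_k * dca_y
        fk_x = -half_k * dcb_x
        fk_y = -half_k * dcb_y
        frc[i, 0] += fi_x
        frc[i, 1] += fi_y
        frc[k, 0] += fk_x
        frc[k, 1] += fk_y
        frc[j, 0] -= fi_x + fk_x
        frc[j, 1] -= fi_y + fk_y

    sig_bb2 = sig_bb * sig_bb
    cut_hh2 = cut_hh * cut_hh
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        if mol[i] == mol[j]:
            continue
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dx, dy = _min_image(dx, dy, lx, ly, perx, pery)
        r2 = dx * dx + dy * dy
        if pk[p] == 0:
            if r2 >= sig_bb2:
                continue
            s2 = sig_bb2 / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            u += 4.0 * eps_bb * (s12 - s6)
            fmag = 24.0 * eps_bb * (2.0 * s12 - s6) / r2
        else:
            if r2 >= cut_hh2:
                continue
            s2 = sig_hh * sig_hh / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            u += 4.0 * eps_hh * (s12 - s6) - shift_hh
            fmag = 24.0 * eps_hh * (2.0 * s12 - s6) / r2
        fx = fmag * dx
        fy = fmag * dy
        # fmag > 0 is repulsive: push j away from i (d points i -> j)
        frc[j, 0] += fx
        frc[j, 1] += fy
        frc[i, 0] -= fx
        frc[i, 1] -= fy
    return u


@njit(cache=True)
def integrate_chunk(pos, vel, frc, inv_mass, dt, lx_steps, cur_lx,
                    ly, perx, pery,
                    bonds, bond_alive, d_e, alpha, r0,
                    angles, angle_alive, k_theta,
                    pi, pj, pk, mol,
                    eps_bb, sig_bb, eps_hh, sig_hh, cut_hh, shift_hh,
                    thermostat, c1, sigma_v, noise):
    """Advance ``len(lx_steps)`` BAOAB steps (velocity Verlet when the
    thermostat is off).  ``frc`` must hold forces for the entry positions;
    it holds forces for the exit positions on return.  Returns (U, lx)."""
    n = pos.shape[0]
    nsteps = lx_steps.shape[0]
    half_dt = 0.5 * dt
    u = 0.0
    for s in range(nsteps):
        new_lx = lx_steps[s]
        if new_lx != cur_lx:
            scale = new_lx / cur_lx
            for i in range(n):
                pos[i, 0] *= scale
            cur_lx = new_lx
        for i in range(n):
            vel[i, 0] += half_dt * frc[i, 0] * inv_mass[i]
            vel[i, 1] += half_dt * frc[i, 1] * inv_mass[i]
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
        if thermostat:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + sigma_v[i] * noise[s, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + sigma_v[i] * noise[s, i, 1]
        for i in range(n):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
        u = forces_energy(pos, frc, cur_lx, ly, perx, pery,
                          bonds, bond_alive, d_e, alpha, r0,
                          angles, angle_alive, k_theta,
                          pi, pj, pk, mol,
                          eps_bb, sig_bb, eps_hh, sig_hh, cut_hh, shift_hh)
        for i in range(n):
            vel[i, 0] += half_dt * frc[i, 0] * inv_mass[i]
            vel[i, 1] += half_dt * frc[i, 1] * inv_mass[i]
    return u, cur_lx


@njit(cache=True)
def max_abs_displacement(pos, ref):
    m = 0.0
    for i in range(pos.shape[0]):
        dx = abs(pos[i, 0] - ref[i, 0])
        dy = abs(pos[i, 1] - ref[i, 1])
        if dx > m:
            m = dx
        if dy > m:
            m = dy
    return m


@njit(cache=True)
def count_bonds_over(pos, bonds, bond_alive, lx, ly, perx, pery, rc):
    """Number of alive bonds longer than rc (fast pre-check)."""
    c = 0
    rc2 = rc * rc
    for b in range(bonds.shape[0]):
        if not bond_alive[b]:
            continue
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dx, dy = _min_image(dx, dy, lx, ly, perx, pery)
        if dx * dx + dy * dy > rc2:
            c += 1
    return c


@njit(cache=True, inline="always")
def _cell_of(x, lo, inv_w, nc, periodic):
    c = int(np.floor((x - lo) * inv_w))
    if periodic:
        c %= nc
        if c < 0:
            c += nc
    else:
        if c < 0:
            c = 0
        elif c >= nc:
            c = nc - 1
    return c


@njit(cache=True)
def build_pairs_cells(pos, lx, ly, perx, pery, bead_type, cut_bb, cut_hh):
    """Cell-list neighbour search; same contract as build_pairs."""
    n = pos.shape[0]
    cell = max(cut_bb, cut_hh)
    # grid spans the box on periodic axes, the bead extent otherwise
    if perx:
        lo_x, ext_x = 0.0, lx
    else:
        lo_x, ext_x = pos[:, 0].min(), max(pos[:, 0].max() - pos[:, 0].min(), cell)
    if pery:
        lo_y, ext_y = 0.0, ly
    else:
        lo_y, ext_y = pos[:, 1].min(), max(pos[:, 1].max() - pos[:, 1].min(), cell)
    ncx = max(1, int(ext_x / cell))
    ncy = max(1, int(ext_y / cell))
    if (perx and ncx < 3) or (pery and ncy < 3):
        return build_pairs(pos, lx, ly, perx, pery, bead_type, cut_bb, cut_hh)
    inv_wx = ncx / ext_x
    inv_wy = ncy / ext_y

    head = np.full(ncx * ncy, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        cx = _cell_of(pos[i, 0], lo_x, inv_wx, ncx, perx)
        cy = _cell_of(pos[i, 1], lo_y, inv_wy, ncy, pery)
        c = cy * ncx + cx
        nxt[i] = head[c]
        head[c] = i

    cut2_bb = cut_bb * cut_bb
    cut2_hh = cut_hh * cut_hh
    cap = 32 * n + 1024
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    pk = np.empty(cap, dtype=np.int8)
    m = 0
    for cy in range(ncy):
        for cx in range(ncx):
            i = head[cy * ncx + cx]
            while i >= 0:
                ti = bead_type[i]
                # same cell + 8 neighbours; j > i avoids double counting
                for oy in range(-1, 2):
                    ny_ = cy + oy
                    if pery:
                        ny_ %= ncy
                    elif ny_ < 0 or ny_ >= ncy:
                        continue
                    for ox in range(-1, 2):
                        nx_ = cx + ox
                        if perx:
                            nx_ %= ncx
                        elif nx_ < 0 or nx_ >= ncx:
                            continue
                        j = head[ny_ * ncx + nx_]
                        while j >= 0:
                            if j > i and bead_type[j] == ti:
                                dx = pos[j, 0] - pos[i, 0]
                                dy = pos[j, 1] - pos[i, 1]
                                dx, dy = _min_image(dx, dy, lx, ly, perx, pery)
                                r2 = dx * dx + dy * dy
                                if (ti == 0 and r2 < cut2_bb) or \
                                        (ti == 1 and r2 < cut2_hh):
                                    if m >= cap:
                                        raise RuntimeError(
                                            "pair capacity exceeded")
                                    pi[m] = i
                                    pj[m] = j
                                    pk[m] = 0 if ti == 0 else 1
                                    m += 1
                            j = nxt[j]
                i = nxt[i]
    return pi[:m].copy(), pj[:m].copy(), pk[:m].copy()
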