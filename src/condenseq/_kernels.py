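"""Numba kernels: neighbor lists, force evaluation, BAOAB Langevin steps.

The force field matches :mod:`condenseq.potentials` exactly (LJ/WCA
nonbonded with minimum-image periodic boundaries, harmonic bonds, 1-cos
bending).  Directly bonded monomer pairs are excluded from the nonbonded
sum.  Integration uses the BAOAB splitting of underdamped Langevin dynamics
(half kick, half drift, Ornstein-Uhlenbeck velocity refresh, half drift,
half kick); immobile (tethered) particles are skipped entirely.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LJ_CUTOFF = 2.5
WCA_CUTOFF2 = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2
LJ_CUTOFF2 = LJ_CUTOFF * LJ_CUTOFF
_LJ_SHIFT_FACTOR = 4.0 * (LJ_CUTOFF ** -12 - LJ_CUTOFF ** -6)


@njit(cache=True, fastmath=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def build_pairs(pos, box, rlist, pairs):
    """Fill ``pairs`` with all i<j within ``rlist`` (minimum image).

    Uses a linked-cell grid when the box accommodates >= 3 cells per axis,
    otherwise brute force.  Returns the pair count, or -1 if ``pairs`` is
    too small.
    """
    n = pos.shape[0]
    cap = pairs.shape[0]
    r2 = rlist * rlist
    ncx = int(box[0] // rlist)
    ncy = int(box[1] // rlist)
    ncz = int(box[2] // rlist)
    # keep the grid commensurate with the particle count (huge sparse boxes)
    max_cells = 8 * n + 1024
    while ncx * ncy * ncz > max_cells:
        if ncx >= ncy and ncx >= ncz and ncx > 3:
            ncx = max(3, ncx // 2)
        elif ncy >= ncz and ncy > 3:
            ncy = max(3, ncy // 2)
        elif ncz > 3:
            ncz = max(3, ncz // 2)
        else:
            break
    count = 0
    if ncx < 3 or ncy < 3 or ncz < 3 or n < 64:
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= box[0] * np.rint(dx / box[0])
                dy -= box[1] * np.rint(dy / box[1])
                dz -= box[2] * np.rint(dz / box[2])
                if dx * dx + dy * dy + dz * dz < r2:
                    if count >= cap:
                        return -1
                    pairs[count, 0] = i
                    pairs[count, 1] = j
                    count += 1
        return count
    csx = box[0] / ncx
    csy = box[1] / ncy
    csz = box[2] / ncz
    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        x = pos[i, 0] % box[0]
        y = pos[i, 1] % box[1]
        z = pos[i, 2] % box[2]
        cx = min(int(x / csx), ncx - 1)
        cy = min(int(y / csy), ncy - 1)
        cz = min(int(z / csz), ncz - 1)
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        nxt[i] = head[c]
        head[c] = i
    for i in range(n):
        c = cell_of[i]
        cz0 = c % ncz
        cy0 = (c // ncz) % ncy
        cx0 = c // (ncy * ncz)
        for ox in range(-1, 2):
            cx = (cx0 + ox) % ncx
            for oy in range(-1, 2):
                cy = (cy0 + oy) % ncy
                for oz in range(-1, 2):
                    cz = (cz0 + oz) % ncz
                    cc = (cx * ncy + cy) * ncz + cz
                    j = head[cc]
                    while j != -1:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= box[0] * np.rint(dx / box[0])
                            dy -= box[1] * np.rint(dy / box[1])
                            dz -= box[2] * np.rint(dz / box[2])
                            if dx * dx + dy * dy + dz * dz < r2:
                                if count >= cap:
                                    return -1
                                pairs[count, 0] = i
                                pairs[count, 1] = j
                                count += 1
                        j = nxt[j]
    return count


@njit(cache=True, fastmath=True)
def compute_forces(pos, box, pairs, n_pairs, types, eps_tab, attract_tab,
                   n_monomers, kb, l0, kappa, forces):
    """Total potential energy; fills ``forces`` with the negative gradient.

    ``eps_tab``/``attract_tab`` are (n_types, n_types) lookup tables.
    Monomers are particles 0..n_monomers-1, chained consecutively; pairs
    (i, i+1) of monomers are bonded and excluded from the nonbonded loop.
    """
    n = pos.shape[0]
    forces[:, :] = 0.0
    pe = 0.0
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        # exclusion: directly bonded monomer neighbors
        if i < n_monomers and j < n_monomers and (j - i == 1 or i - j == 1):
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        eps = eps_tab[types[i], types[j]]
        if eps == 0.0:
            continue
        attract = attract_tab[types[i], types[j]]
        if attract:
            if r2 >= LJ_CUTOFF2:
                continue
        else:
            if r2 >= WCA_CUTOFF2:
                continue
        inv2 = 1.0 / r2
        inv6 = inv2 * inv2 * inv2
        inv12 = inv6 * inv6
        if attract:
            pe += 4.0 * eps * (inv12 - inv6) - eps * _LJ_SHIFT_FACTOR
        else:
            pe += 4.0 * eps * (inv12 - inv6) + eps
        fmag = 24.0 * eps * (2.0 * inv12 - inv6) * inv2
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    # harmonic bonds along the chain (unwrapped coordinates: no min image)
    for i in range(n_monomers - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        dl = l - l0
        pe += 0.5 * kb * dl * dl
        f = -kb * dl / l
        forces[i + 1, 0] += f * dx
        forces[i + 1, 1] += f * dy
        forces[i + 1, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
    # bending: 1 - cos(theta) over consecutive bond pairs
    if kappa != 0.0:
        for m in range(1, n_monomers - 1):
            b1x = pos[m, 0] - pos[m - 1, 0]
            b1y = pos[m, 1] - pos[m - 1, 1]
            b1z = pos[m, 2] - pos[m - 1, 2]
            b2x = pos[m + 1, 0] - pos[m, 0]
            b2y = pos[m + 1, 1] - pos[m, 1]
            b2z = pos[m + 1, 2] - pos[m, 2]
            l1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            l2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            il12 = 1.0 / (l1 * l2)
            ct = (b1x * b2x + b1y * b2y + b1z * b2z) * il12
            pe += kappa * (1.0 - ct)
            g1x = b2x * il12 - ct * b1x / (l1 * l1)
            g1y = b2y * il12 - ct * b1y / (l1 * l1)
            g1z = b2z * il12 - ct * b1z / (l1 * l1)
            g2x = b1x * il12 - ct * b2x / (l2 * l2)
            g2y = b1y * il12 - ct * b2y / (l2 * l2)
            g2z = b1z * il12 - ct * b2z / (l2 * l2)
            forces[m - 1, 0] += -kappa * g1x
            forces[m - 1, 1] += -kappa * g1y
            forces[m - 1, 2] += -kappa * g1z
            forces[m + 1, 0] += kappa * g2x
            forces[m + 1, 1] += kappa * g2y
            forces[m + 1, 2] += kappa * g2z
            forces[m, 0] += kappa * (g1x - g2x)
            forces[m, 1] += kappa * (g1y - g2y)
            forces[m, 2] += kappa * (g1z - g2z)
    return pe


@njit(cache=True, fastmath=True)
def baoab_chunk(pos, vel, forces, mobile, box, pairs, n_pairs, types,
                eps_tab, attract_tab, n_monomers, kb, l0, kappa,
                dt, gamma, temperature, nsteps):
    """Advance ``nsteps`` BAOAB Langevin steps with a frozen neighbor list.

    Returns the potential energy after the last step.  ``forces`` must hold
    the forces for the entering positions and is left consistent on exit.
    """
    n = pos.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(temperature * (1.0 - c1 * c1))
    pe = 0.0
    for s in range(nsteps):
        for i in range(n):
            if mobile[i]:
                for d in range(3):
                    vel[i, d] += 0.5 * dt * forces[i, d]
                    pos[i, d] += 0.5 * dt * vel[i, d]
        for i in range(n):
            if mobile[i]:
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + c2 * np.random.normal()
                    pos[i, d] += 0.5 * dt * vel[i, d]
        pe = compute_forces(pos, box, pairs, n_pairs, types, eps_tab,
                            attract_tab, n_monomers, kb, l0, kappa, forces)
        for i in range(n):
            if mobile[i]:
                for d in range(3):
                    vel[i, d] += 0.5 * dt * forces[i, d]
    return pe


@njit(cache=True, fastmath=True)
def overdamped_chunk(pos, forces, mobile, box, pairs, n_pairs, types,
                     eps_tab, attract_tab, n_monomers, kb, l0, kappa,
                     dt, gamma, temperature, nsteps):
    """Overdamped Euler-Maruyama steps: dx = F/gamma dt + sqrt(2T dt/gamma) xi.

    Inertia is dropped entirely; provided for comparison with the default
    underdamped BAOAB integrator.  Returns the final potential energy.
    """
    n = pos.shape[0]
    mob = dt / gamma
    noise = np.sqrt(2.0 * temperature * dt / gamma)
    pe = 0.0
    for s in range(nsteps):
        pe = compute_forces(pos, box, pairs, n_pairs, types, eps_tab,
                            attract_tab, n_monomers, kb, l0, kappa, forces)
        for i in range(n):
            if mobile[i]:
                for d in range(3):
                    pos[i, d] += mob * forces[i, d] + noise * np.random.normal()
    return pe
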