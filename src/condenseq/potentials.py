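"""Pair and bonded potentials (pure-numpy reference implementations).

Nonbonded interactions follow the standard bead-spring conventions:

* attractive pairs (protein-protein, monomer-protein): Lennard-Jones with
  well depth ``eps``, cut at 2.5 sigma and shifted so the energy vanishes at
  the cutoff;
* repulsive pairs (monomer-monomer, and any pair with eps = 0): WCA, i.e.
  Lennard-Jones truncated at its minimum 2^(1/6) sigma and shifted.

Bonded terms: harmonic bonds E = kb/2 (l - l0)^2 and a discrete worm-like
chain bending energy E = kappa (1 - cos theta) per consecutive bond pair.
With kappa expressed in kBT this gives a persistence length of ~kappa bonds
in the stiff limit.

The numba kernels in :mod:`condenseq._kernels` implement the same force
field; these functions are the readable reference used for per-monomer
energy profiles and in cross-checks.
"""

from __future__ import annotations

import numpy as np

LJ_CUTOFF = 2.5
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)
# 4 * [(1/2.5)^12 - (1/2.5)^6]; multiply by eps for the LJ shift at cutoff
_LJ_SHIFT_FACTOR = 4.0 * (LJ_CUTOFF ** -12 - LJ_CUTOFF ** -6)


def pair_energy(r, kind: str, eps: float):
    """Nonbonded pair energy at separation ``r`` (sigma), in kBT.

    ``kind`` is ``"attractive"`` (shifted LJ, cutoff 2.5 sigma) or
    ``"repulsive"`` (WCA).  Vectorized over ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    if kind == "attractive":
        cutoff = LJ_CUTOFF
        shift = eps * _LJ_SHIFT_FACTOR
    elif kind == "repulsive":
        cutoff = WCA_CUTOFF
        shift = -eps  # WCA: U(2^(1/6)) = -eps before shift
    else:
        raise ValueError(f"kind must be 'attractive' or 'repulsive', got {kind!r}")
    inv6 = r ** -6.0
    u = np.where(r < cutoff, 4.0 * eps * (inv6 ** 2 - inv6) - shift, 0.0)
    return u if u.ndim else float(u)


def pair_force_mag(r: float, kind: str, eps: float) -> float:
    """Magnitude of -dU/dr (positive = repulsive), reference scalar form."""
    if r <= 0:
        raise ValueError("pair separation must be positive")
    cutoff = LJ_CUTOFF if kind == "attractive" else WCA_CUTOFF
    if r >= cutoff:
        return 0.0
    inv6 = r ** -6.0
    return 24.0 * eps * (2.0 * inv6 ** 2 - inv6) / r


def bonded_energy_forces(positions: np.ndarray, bonds: np.ndarray,
                         angles: np.ndarray, kb: float, kappa: float,
                         l0: float = 1.0) -> tuple[float, np.ndarray]:
    """Total bonded energy and exact per-particle forces.

    ``bonds`` is an (nb, 2) index array, ``angles`` an (na, 3) array of
    consecutive triplets.  Forces are the analytic negative gradients.
    """
    pos = np.asarray(positions, dtype=float)
    forces = np.zeros_like(pos)
    energy = 0.0
    for i, j in np.asarray(bonds, dtype=int).reshape(-1, 2):
        d = pos[j] - pos[i]
        l = np.linalg.norm(d)
        dl = l - l0
        energy += 0.5 * kb * dl * dl
        f = -kb * dl * d / l  # force on j
        forces[j] += f
        forces[i] -= f
    for a, b, c in np.asarray(angles, dtype=int).reshape(-1, 3):
        b1 = pos[b] - pos[a]
        b2 = pos[c] - pos[b]
        l1 = np.linalg.norm(b1)
        l2 = np.linalg.norm(b2)
        ct = float(b1 @ b2) / (l1 * l2)
        energy += kappa * (1.0 - ct)
        # dcos/db1 and dcos/db2
        g1 = b2 / (l1 * l2) - ct * b1 / l1 ** 2
        g2 = b1 / (l1 * l2) - ct * b2 / l2 ** 2
        forces[a] += -kappa * g1
        forces[c] += kappa * g2
        forces[b] += kappa * (g1 - g2)
    return energy, forces


def min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement for a fully periodic box."""
    return d - box * np.round(d / box)
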