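"""Brownian-dynamics engine for tethered DNA + protein-bead systems.

The DNA is a semiflexible bead-spring chain (one bead = 10 bp) whose two end
monomers are pinned on the long axis of a fully periodic box at separation
Re = Re' * s; proteins are free beads of the same size.  Dynamics are
underdamped Langevin (BAOAB splitting) at T = 1 kBT with damping
gamma = 0.1 / tau and time step 0.01 tau by default.

The standard experiment runs in three phases: a protein-free equilibration
of the tethered chain, an equilibration after proteins are introduced
(stopped early once both the potential energy and the largest-cluster size
plateau), and a production phase from which frames are saved for analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from . import _kernels
from .affinity import AffinityProfile, build_block_profile
from .config import ExperimentConfig

PROTEIN_LABEL = "P"
_SKIN = 0.8
_REBUILD_EVERY = 10


class IntegrationError(RuntimeError):
    pass


class DensityError(RuntimeError):
    pass


@dataclass
class InteractionTable:
    """Symmetric nonbonded lookup tables over particle types.

    Types 0..K-1 are the distinct monomer affinity levels (ascending), type
    K is the protein.  ``eps[i, j]`` is the well depth in kBT; ``attract``
    selects shifted-LJ (True) vs WCA (False).  Monomer-monomer pairs are
    purely repulsive (WCA, eps 1); monomer-protein pairs attract with the
    level's eps_MP; a zero eps_MP degrades to pure excluded volume.
    """

    eps: np.ndarray
    attract: np.ndarray
    monomer_levels: np.ndarray  # kBT per monomer type
    eps_pp: float

    @classmethod
    def from_profile(cls, profile: AffinityProfile, eps_pp: float,
                     eps_mp_scale: float = 1.0) -> "InteractionTable":
        levels = np.unique(profile.affinities) * eps_mp_scale
        k = levels.size
        eps = np.zeros((k + 1, k + 1))
        attract = np.zeros((k + 1, k + 1), dtype=np.bool_)
        eps[:k, :k] = 1.0  # monomer-monomer WCA
        for t in range(k):
            if levels[t] > 0:
                eps[t, k] = eps[k, t] = levels[t]
                attract[t, k] = attract[k, t] = True
            else:
                eps[t, k] = eps[k, t] = 1.0
        eps[k, k] = eps_pp if eps_pp > 0 else 1.0
        attract[k, k] = eps_pp > 0
        return cls(eps, attract, levels, eps_pp)

    def monomer_types(self, profile: AffinityProfile,
                      eps_mp_scale: float = 1.0) -> np.ndarray:
        """Type id per monomer for a profile compatible with this table."""
        return np.searchsorted(self.monomer_levels,
                               profile.affinities * eps_mp_scale)

    @property
    def protein_type(self) -> int:
        return self.monomer_levels.size


@dataclass
class SystemState:
    """Instantaneous particle system: Nm chain monomers then Np proteins."""

    positions: np.ndarray   # (N, 3), sigma, unwrapped
    velocities: np.ndarray  # (N, 3)
    types: np.ndarray       # (N,) int, indices into an InteractionTable
    n_monomers: int
    box: np.ndarray         # (3,)
    mobile: np.ndarray      # (N,) bool; False for tethered monomers
    time: float = 0.0

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.n_particles - self.n_monomers

    @property
    def bonds(self) -> np.ndarray:
        i = np.arange(self.n_monomers - 1)
        return np.column_stack([i, i + 1])

    @property
    def angles(self) -> np.ndarray:
        i = np.arange(1, self.n_monomers - 1)
        return np.column_stack([i - 1, i, i + 1])

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.types.copy(), self.n_monomers,
                           self.box.copy(), self.mobile.copy(), self.time)


@dataclass
class Trajectory:
    """Saved frames of a run (positions only; velocities are not stored)."""

    frames: np.ndarray      # (F, N, 3)
    times: np.ndarray       # (F,)
    types: np.ndarray       # (N,) int
    type_labels: list[str]  # per type id, e.g. "M2.25", "P"
    n_monomers: int
    box: np.ndarray
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_particles, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_particles(self) -> int:
        return self.frames.shape[1]

    def bond_lengths(self) -> np.ndarray:
        """(F, Nm-1) bond lengths of the chain in every frame."""
        mono = self.frames[:, :self.n_monomers]
        return np.linalg.norm(np.diff(mono, axis=1), axis=2)


def _arc_chain(n: int, bond_length: float, re: float, azimuth: float,
               center: np.ndarray) -> np.ndarray:
    """Monomer positions on a circular arc of contour ~s with chord re.

    The arc lies in the plane spanned by the box long axis (z) and the
    direction given by ``azimuth``; for re ~ s it degenerates to a straight
    line.  This is only a starting shape -- the protein-free equilibration
    randomizes it.
    """
    s = (n - 1) * bond_length
    pos = np.zeros((n, 3))
    t = np.linspace(0.0, 1.0, n)
    if re >= 0.999 * s:
        pos[:, 2] = (t - 0.5) * re
    else:
        # sin(alpha)/alpha = re/s, alpha in (0, pi)
        f = lambda a: np.sin(a) / a - re / s
        alpha = brentq(f, 1e-9, np.pi - 1e-9)
        radius = s / (2 * alpha)
        ang = (2 * t - 1.0) * alpha
        pos[:, 2] = radius * np.sin(ang)
        sag = radius * (np.cos(ang) - np.cos(alpha))
        pos[:, 0] = sag * np.cos(azimuth)
        pos[:, 1] = sag * np.sin(azimuth)
    return pos + center


def _wlc_chain(n: int, bond_length: float, kappa: float,
               rng: np.random.Generator, center: np.ndarray) -> np.ndarray:
    """Sample an ideal discrete worm-like chain (no excluded volume).

    Bond angles follow the Boltzmann weight exp(-kappa (1 - cos theta))
    with the sin(theta) surface measure, which has the closed-form inverse
    CDF used below; azimuths are uniform.
    """
    tangents = np.zeros((n - 1, 3))
    tangents[0] = np.array([0.0, 0.0, 1.0])
    for b in range(1, n - 1):
        u = rng.random()
        if kappa < 1e-9:
            ct = 2 * u - 1
        else:
            ct = 1.0 + np.log(u + (1 - u) * np.exp(-2 * kappa)) / kappa
        st = np.sqrt(max(0.0, 1.0 - ct * ct))
        phi = rng.uniform(0, 2 * np.pi)
        t_prev = tangents[b - 1]
        # orthonormal frame around t_prev
        a = np.array([1.0, 0.0, 0.0]) if abs(t_prev[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(t_prev, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t_prev, e1)
        tangents[b] = ct * t_prev + st * (np.cos(phi) * e1 + np.sin(phi) * e2)
    pos = np.zeros((n, 3))
    pos[1:] = np.cumsum(tangents * bond_length, axis=0)
    return pos - pos.mean(axis=0) + center


def _place_proteins(n_proteins: int, existing: np.ndarray, box: np.ndarray,
                    rng: np.random.Generator, min_dist: float = 0.9,
                    max_rounds: int = 200,
                    near_chain_fraction: float = 0.0,
                    near_radius: float = 4.0) -> np.ndarray:
    """Random protein positions with overlap rejection (PBC).

    A ``near_chain_fraction`` of the proteins is drawn within
    ``near_radius`` sigma of randomly chosen chain beads instead of
    uniformly; this pre-seeds nucleation on the chain (the equilibrium
    state is unchanged, but desk-scale runs on taut chains otherwise spend
    most of their budget waiting for a nucleation event).
    """
    if n_proteins == 0:
        return np.zeros((0, 3))

    def sample(k: int) -> np.ndarray:
        n_near = int(round(k * near_chain_fraction)) if len(existing) else 0
        pts = rng.uniform(0, 1, size=(k, 3)) * box
        if n_near:
            beads = existing[rng.integers(0, len(existing), n_near)]
            offs = rng.normal(0, 1, (n_near, 3))
            offs /= np.linalg.norm(offs, axis=1, keepdims=True)
            offs *= near_radius * rng.uniform(0.3, 1.0, (n_near, 1))
            pts[:n_near] = beads + offs
        return pts

    placed = sample(n_proteins)
    anchor = np.ascontiguousarray(existing % box)
    for _ in range(max_rounds):
        tree_exist = cKDTree(anchor, boxsize=box) if len(anchor) else None
        bad = np.zeros(n_proteins, dtype=bool)
        if tree_exist is not None:
            hits = tree_exist.query_ball_point(placed % box, min_dist)
            bad |= np.array([len(h) > 0 for h in hits])
        tree_self = cKDTree(placed % box, boxsize=box)
        for i, j in tree_self.query_pairs(min_dist):
            bad[max(i, j)] = True
        if not bad.any():
            return placed
        placed[bad] = sample(int(bad.sum()))
    raise DensityError(
        f"could not place {n_proteins} proteins at min distance {min_dist} "
        f"sigma after {max_rounds} rejection rounds; box too dense")


def type_labels_for(table: InteractionTable) -> list[str]:
    return [f"M{lv:g}" for lv in table.monomer_levels] + [PROTEIN_LABEL]


def init_system(config: ExperimentConfig, profile: AffinityProfile,
                seed: int | None = None, tethered: bool = True,
                with_proteins: bool = True,
                chain_positions: np.ndarray | None = None,
                ) -> tuple[SystemState, InteractionTable]:
    """Build the initial particle system for a run.

    The chain starts on a smooth arc between the tether anchors (or as an
    ideal worm-like-chain sample when untethered) unless an equilibrated
    chain is injected via ``chain_positions``; proteins are placed
    uniformly at random with overlap rejection against the actual chain.
    Deterministic given ``seed`` (defaults to ``config.seed``); placement
    and thermostat noise use independent substreams of the same seed.
    """
    if profile.length != config.n_monomers:
        raise ValueError(
            f"profile length {profile.length} != config n_monomers {config.n_monomers}")
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_chain, rng_prot, rng_vel = [np.random.default_rng(s) for s in ss.spawn(3)]

    table = InteractionTable.from_profile(profile, config.eps_pp, config.eps_mp_scale)
    box = np.asarray(config.box, dtype=float)
    center = box / 2.0
    n = config.n_monomers
    if chain_positions is not None:
        chain = np.array(chain_positions, dtype=float)
        if chain.shape != (n, 3):
            raise ValueError(f"chain_positions must be ({n}, 3)")
    elif tethered:
        chain = _arc_chain(n, config.bond_length, config.tether_separation,
                           rng_chain.uniform(0, 2 * np.pi), center)
    else:
        chain = _wlc_chain(n, config.bond_length, config.kappa, rng_chain, center)
    np_prot = config.protein_count if with_proteins else 0
    proteins = _place_proteins(
        np_prot, chain, box, rng_prot,
        near_chain_fraction=config.protein_near_chain_fraction)

    positions = np.vstack([chain, proteins])
    types = np.concatenate([
        table.monomer_types(profile, config.eps_mp_scale),
        np.full(np_prot, table.protein_type, dtype=int),
    ])
    mobile = np.ones(len(positions), dtype=bool)
    if tethered:
        mobile[0] = mobile[n - 1] = False
    velocities = rng_vel.normal(0.0, np.sqrt(config.temperature),
                                size=positions.shape)
    velocities[~mobile] = 0.0
    state = SystemState(positions, velocities, types.astype(np.int64), n,
                        box, mobile)
    return state, table


def integrate(state: SystemState, table: InteractionTable, nsteps: int,
              dt: float = 0.01, temperature: float = 1.0, gamma: float = 0.1,
              seed: int | None = None, kb: float = 100.0, kappa: float = 15.0,
              bond_length: float = 1.0, save_every: int | None = None,
              overdamped: bool = False,
              ) -> tuple[SystemState, np.ndarray, np.ndarray]:
    """Advance ``nsteps`` of Langevin dynamics in place.

    Returns ``(state, frames, frame_times)``; frames are saved every
    ``save_every`` steps (none if None).  The thermostat noise stream is
    seeded once per call, so repeated calls with the same seed and inputs
    are bit-reproducible.  ``overdamped`` switches from the default
    underdamped BAOAB integrator to inertialess Euler-Maruyama dynamics
    (velocities are then ignored).
    """
    if seed is not None:
        _kernels.seed_rng(int(seed) % (2 ** 31))
    pos = state.positions
    n = state.n_particles
    rlist = _kernels.LJ_CUTOFF + _SKIN
    cap = max(4096, n * 96)
    pairs = np.empty((cap, 2), dtype=np.int64)
    forces = np.empty_like(pos)

    def rebuild() -> int:
        nonlocal pairs, cap
        while True:
            npairs = _kernels.build_pairs(pos, state.box, rlist, pairs)
            if npairs >= 0:
                return npairs
            cap *= 2
            pairs = np.empty((cap, 2), dtype=np.int64)

    n_pairs = rebuild()
    _kernels.compute_forces(pos, state.box, pairs, n_pairs, state.types,
                            table.eps, table.attract, state.n_monomers,
                            kb, bond_length, kappa, forces)
    frames, frame_times = [], []
    done = 0
    next_check = 0
    while done < nsteps:
        chunk = min(_REBUILD_EVERY, nsteps - done)
        if save_every is not None:
            to_save = save_every - (done % save_every)
            chunk = min(chunk, to_save)
        if overdamped:
            _kernels.overdamped_chunk(pos, forces, state.mobile, state.box,
                                      pairs, n_pairs, state.types, table.eps,
                                      table.attract, state.n_monomers, kb,
                                      bond_length, kappa, dt, gamma,
                                      temperature, chunk)
        else:
            _kernels.baoab_chunk(pos, state.velocities, forces, state.mobile,
                                 state.box, pairs, n_pairs, state.types,
                                 table.eps, table.attract, state.n_monomers,
                                 kb, bond_length, kappa, dt, gamma,
                                 temperature, chunk)
        done += chunk
        state.time += chunk * dt
        if save_every is not None and done % save_every == 0:
            frames.append(pos.copy())
            frame_times.append(state.time)
        if done >= next_check:
            if not np.isfinite(pos).all():
                raise IntegrationError(
                    f"non-finite coordinates after step {done}; "
                    "the time step is likely too large for the stiffest force")
            next_check = done + 2000
        n_pairs = rebuild()
    fr = np.array(frames) if frames else np.zeros((0, n, 3))
    return state, fr, np.array(frame_times)


def largest_cluster_size(positions: np.ndarray, box: np.ndarray,
                         radius: float = 1.5) -> int:
    """Size of the largest connected component of the radius graph (PBC)."""
    tree = cKDTree(positions % box, boxsize=box)
    n = len(positions)
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    return int(np.bincount(roots).max()) if n else 0


def run_experiment(config: ExperimentConfig, profile: AffinityProfile | None = None,
                   seed: int | None = None, tethered: bool = True,
                   with_proteins: bool = True,
                   initial_chain: np.ndarray | None = None,
                   log: list | None = None) -> Trajectory:
    """Full protocol: chain equilibration, protein equilibration, production.

    ``initial_chain`` can inject a pre-equilibrated DNA configuration (the
    replicate protocol equilibrates the bare chain once per seed and reuses
    it).  Equilibration with proteins stops early when both the potential
    energy and the largest-cluster size change by < 2% across two
    consecutive windows of 10% of the budget.
    """
    if profile is None:
        profile = build_block_profile(config.model, config.n_monomers)
    seed = config.seed if seed is None else seed
    state, table = init_system(config, profile, seed=seed, tethered=tethered,
                               with_proteins=False)
    kw = dict(dt=config.dt, temperature=config.temperature, gamma=config.gamma,
              kb=config.kb, kappa=config.kappa, bond_length=config.bond_length)
    if initial_chain is not None:
        state.positions[:config.n_monomers] = initial_chain
    elif config.dna_equil_steps > 0:
        integrate(state, table, config.dna_equil_steps, seed=seed * 7 + 1, **kw)
        if log is not None:
            log.append({"phase": "dna_equil", "step": config.dna_equil_steps,
                        "time": state.time})

    if with_proteins and config.protein_count > 0:
        chain = state.positions[:config.n_monomers].copy()
        t0 = state.time
        state, table = init_system(config, profile, seed=seed, tethered=tethered,
                                   with_proteins=True, chain_positions=chain)
        state.time = t0
        # plateau-checked equilibration in windows of 10% of the budget
        window = config.equil_steps // 10
        prev: tuple[float, float] | None = None
        stable = 0
        forces_scratch = np.empty_like(state.positions)
        for w in range(10 if window > 0 else 0):
            integrate(state, table, window, seed=seed * 7 + 2 + w, **kw)
            pe = _total_pe(state, table, config, forces_scratch)
            lcs = largest_cluster_size(state.positions, state.box)
            if log is not None:
                log.append({"phase": "equil", "step": (w + 1) * window,
                            "pe": pe, "largest_cluster": lcs})
            if prev is not None:
                d_pe = abs(pe - prev[0]) / max(abs(prev[0]), 1e-9)
                d_cl = abs(lcs - prev[1]) / max(prev[1], 1.0)
                stable = stable + 1 if (d_pe < 0.02 and d_cl < 0.02) else 0
                if stable >= 2:
                    break
            prev = (pe, lcs)

    state, frames, times = integrate(
        state, table, config.production_steps, seed=seed * 7 + 97,
        save_every=config.save_interval, **kw)
    if log is not None:
        log.append({"phase": "production", "step": config.production_steps,
                    "n_frames": len(frames)})
    cfg = config.to_dict()
    cfg["config_hash"] = config.config_hash()
    cfg["tethered"] = tethered
    return Trajectory(frames, times, state.types.copy(),
                      type_labels_for(table), config.n_monomers,
                      state.box.copy(), cfg, seed)


def _total_pe(state: SystemState, table: InteractionTable,
              config: ExperimentConfig, forces: np.ndarray) -> float:
    rlist = _kernels.LJ_CUTOFF + _SKIN
    cap = max(4096, state.n_particles * 96)
    while True:
        pairs = np.empty((cap, 2), dtype=np.int64)
        n_pairs = _kernels.build_pairs(state.positions, state.box, rlist, pairs)
        if n_pairs >= 0:
            break
        cap *= 2
    return _kernels.compute_forces(
        state.positions, state.box, pairs, n_pairs, state.types, table.eps,
        table.attract, state.n_monomers, config.kb, config.bond_length,
        config.kappa, forces)
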