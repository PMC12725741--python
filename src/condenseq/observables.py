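"""Quantitative readouts: occupancy, interfacial affinity, capillary force,
per-monomer energies, kymographs, coarsening kinetics, persistence length.

Force convention.  Tethering stretches the chain's harmonic bonds, so mean
bond elongation reads out tension: with free-end mean bond length l0_bar,
tethered mean lt_bar and (with proteins) mean over bonds outside every
condensate ltp_bar,

    F_DNA         = kb * (lt_bar  - l0_bar)      (tether force)
    F_DNA,protein = kb * (ltp_bar - lt_bar)      (force with proteins)
    F             = F_DNA,protein - F_DNA        (capillary force)

averaged over the analysis frames; replicate spread is reported as the
standard deviation over independent initial conditions.  Forces are emitted
both in kBT/sigma and in pN (1 kBT/sigma ~ 1.209 pN for 10-bp beads).

Interfacial affinity.  Each monomer's occupancy Pm is the fraction of
analysis frames it spends inside a detected condensate; interface monomers
satisfy 0.1 < Pm <= 1 (as an alternative, an upper bound of 0.9 excludes
permanently interior monomers), and the interfacial affinity is their
occupancy-weighted mean binding energy

    Ia = sum_m eps_mp(m) Pm(m) / sum_m Pm(m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affinity import AffinityProfile
from .detect import CondensateRecord, track_condensates
from .units import PN_PER_KBT_SIGMA


# --------------------------------------------------------------------------
# occupancy (per-monomer probability of being inside a condensate)

@dataclass
class OccupancyProfile:
    pm: np.ndarray                # (Nm,), in [0, 1]
    membership: np.ndarray        # (omega_c, Nm) bool: s_{m,c}
    omega_c: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"monomer": np.arange(len(self.pm)), "Pm": self.pm})


def membership_matrix(detections: list[list[CondensateRecord]],
                      n_monomers: int) -> np.ndarray:
    """s_{m,c}: 1 when monomer m lies inside any condensate at frame c."""
    s = np.zeros((len(detections), n_monomers), dtype=bool)
    for c, records in enumerate(detections):
        for rec in records:
            mono = rec.members[rec.members < n_monomers]
            s[c, mono] = True
    return s


def occupancy(detections: list[list[CondensateRecord]],
              n_monomers: int) -> OccupancyProfile:
    """Occupancy probability Pm = sum_c s_{m,c} / Omega_c."""
    omega = len(detections)
    if omega == 0:
        raise ValueError("no frames: occupancy undefined")
    s = membership_matrix(detections, n_monomers)
    return OccupancyProfile(s.mean(axis=0), s, omega)


# --------------------------------------------------------------------------
# interfacial affinity

@dataclass
class InterfaceSide:
    core_span: tuple[int, int]
    side: str                 # "left" | "right"
    monomers: np.ndarray
    ia: float                 # kBT


@dataclass
class InterfaceResult:
    sides: list[InterfaceSide]
    ia_mean: float            # average over all interface sides, kBT
    ia_global: float          # Eq-style weighted mean over the whole set
    n_interface: int          # NmI
    interface_monomers: np.ndarray


def _weighted_affinity(eps: np.ndarray, pm: np.ndarray) -> float:
    return float(np.sum(eps * pm) / np.sum(pm))


def interfacial_affinity(occ: OccupancyProfile, profile: AffinityProfile,
                         upper: float = 1.0, lower: float = 0.1,
                         core_threshold: float = 0.9) -> InterfaceResult:
    """Occupancy-weighted interface affinity, split by condensate side.

    The interface set is all monomers with ``lower < Pm <= upper`` (the
    default keeps permanently interior monomers; pass ``upper=0.9`` for the
    strict-interface variant).  Condensate cores are the maximal contiguous
    runs with Pm >= ``core_threshold``; each interface monomer is assigned
    to the nearest core and to its left or right side, and the per-side Ia
    values are averaged.
    """
    pm = occ.pm
    eps = profile.affinities
    if len(pm) != len(eps):
        raise ValueError("occupancy and affinity profile lengths differ")
    iface = np.flatnonzero((pm > lower) & (pm <= upper))
    if len(iface) == 0:
        raise ValueError(
            "empty interface set: Pm summary "
            f"min={pm.min():.3f} max={pm.max():.3f} mean={pm.mean():.3f}")
    ia_global = _weighted_affinity(eps[iface], pm[iface])

    core_mask = pm >= core_threshold
    cores: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(core_mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            cores.append((start, i - 1))
            start = None
    if start is not None:
        cores.append((start, len(pm) - 1))

    sides: list[InterfaceSide] = []
    if cores:
        centers = np.array([(a + b) / 2 for a, b in cores])
        assign = np.argmin(np.abs(iface[:, None] - centers[None, :]), axis=1)
        for ci, (a, b) in enumerate(cores):
            mine = iface[assign == ci]
            mid = (a + b) / 2
            for side_name, sel in (("left", mine[mine <= mid]),
                                   ("right", mine[mine > mid])):
                if len(sel):
                    sides.append(InterfaceSide(
                        (a, b), side_name, sel,
                        _weighted_affinity(eps[sel], pm[sel])))
    if sides:
        ia_mean = float(np.mean([s.ia for s in sides]))
    else:
        ia_mean = ia_global
    return InterfaceResult(sides, ia_mean, ia_global, len(iface), iface)


# --------------------------------------------------------------------------
# force pipeline

@dataclass
class ForceResult:
    l0_mean: float            # free-end mean bond length, sigma
    lt_mean: float            # tethered (bare) mean bond length
    ltp_mean: float           # with proteins, bonds outside condensates
    f_dna: float              # kBT/sigma
    f_dna_protein: float      # kBT/sigma
    f: float                  # capillary force, kBT/sigma
    kb: float
    n_frames: int = 0

    @property
    def f_pn(self) -> float:
        return self.f * PN_PER_KBT_SIGMA

    @property
    def f_dna_pn(self) -> float:
        return self.f_dna * PN_PER_KBT_SIGMA

    @property
    def f_dna_protein_pn(self) -> float:
        return self.f_dna_protein * PN_PER_KBT_SIGMA


def force_from_bond_means(ltp_mean: float, lt_mean: float, l0_mean: float,
                          kb: float, n_frames: int = 0) -> ForceResult:
    """Assemble the force readouts from the three mean bond lengths."""
    if min(ltp_mean, lt_mean, l0_mean) <= 0:
        raise ValueError("mean bond lengths must be positive")
    f_dna = kb * (lt_mean - l0_mean)
    f_dna_p = kb * (ltp_mean - lt_mean)
    return ForceResult(l0_mean, lt_mean, ltp_mean, f_dna, f_dna_p,
                       f_dna_p - f_dna, kb, n_frames)


def mean_bond_length(traj) -> float:
    """Frame-averaged mean bond length of the chain."""
    return float(traj.bond_lengths().mean())


def tether_force(traj_tethered_bare, traj_free_bare, kb: float) -> float:
    """F_DNA = kb (lt_bar - l0_bar), in kBT/sigma."""
    if traj_tethered_bare.n_monomers != traj_free_bare.n_monomers:
        raise ValueError("trajectories have different chain lengths")
    return kb * (mean_bond_length(traj_tethered_bare)
                 - mean_bond_length(traj_free_bare))


def outside_bond_mean(traj, detections: list[list[CondensateRecord]]) -> float:
    """Mean length of bonds with both endpoint monomers outside every
    condensate, averaged per frame then over frames."""
    if len(detections) != traj.n_frames:
        raise ValueError("detection output not aligned with frames")
    lengths = traj.bond_lengths()
    s = membership_matrix(detections, traj.n_monomers)
    per_frame = []
    for c in range(traj.n_frames):
        outside = ~s[c]
        keep = outside[:-1] & outside[1:]  # both endpoints outside
        if keep.any():
            per_frame.append(lengths[c, keep].mean())
    if not per_frame:
        raise ValueError("all bonds inside condensates in every frame; "
                         "outside-bond force undefined")
    return float(np.mean(per_frame))


def capillary_force(traj_with_proteins, detections, traj_tethered_bare,
                    kb: float, traj_free_bare=None) -> ForceResult:
    """Eqs-style capillary force from one replicate.

    Without a free-end trajectory the tether force F_DNA is taken as zero
    (lt_bar is then used as the free reference), which leaves the
    with-protein excess force unchanged.
    """
    lt = mean_bond_length(traj_tethered_bare)
    l0 = mean_bond_length(traj_free_bare) if traj_free_bare is not None else lt
    ltp = outside_bond_mean(traj_with_proteins, detections)
    return force_from_bond_means(ltp, lt, l0, kb,
                                 n_frames=traj_with_proteins.n_frames)


def aggregate_forces(results: list[ForceResult]) -> dict:
    """Replicate mean and standard deviation of the force readouts."""
    if not results:
        raise ValueError("no replicates to aggregate")
    fs = np.array([r.f for r in results])
    return {
        "n_replicates": len(results),
        "f_mean_kbt_sigma": float(fs.mean()),
        "f_std_kbt_sigma": float(fs.std(ddof=1)) if len(fs) > 1 else 0.0,
        "f_mean_pn": float(fs.mean() * PN_PER_KBT_SIGMA),
        "f_std_pn": (float(fs.std(ddof=1) * PN_PER_KBT_SIGMA)
                     if len(fs) > 1 else 0.0),
        "f_dna_mean_kbt_sigma": float(np.mean([r.f_dna for r in results])),
        "f_dna_protein_mean_kbt_sigma": float(np.mean([r.f_dna_protein
                                                       for r in results])),
    }


# --------------------------------------------------------------------------
# per-monomer potential energy

def monomer_potential_profile(positions: np.ndarray, types: np.ndarray,
                              table, n_monomers: int, box: np.ndarray,
                              kb: float = 100.0, kappa: float = 15.0,
                              bond_length: float = 1.0) -> np.ndarray:
    """Per-monomer potential energy along the contour, kBT.

    Every nonbonded pair energy is split half-and-half between its
    endpoints (only monomer halves enter the profile); each monomer also
    collects half of its two bond energies and the bending energy centered
    on it.
    """
    from scipy.spatial import cKDTree
    from .potentials import LJ_CUTOFF, pair_energy

    pos = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    prof = np.zeros(n_monomers)
    tree = cKDTree(pos % box, boxsize=box)
    for i, j in tree.query_pairs(LJ_CUTOFF):
        if i < n_monomers and j < n_monomers and abs(i - j) == 1:
            continue  # bonded exclusion
        if i >= n_monomers and j >= n_monomers:
            continue  # protein-protein: no monomer share
        d = pos[i] - pos[j]
        d -= box * np.round(d / box)
        r = float(np.linalg.norm(d))
        eps = table.eps[types[i], types[j]]
        if eps == 0.0:
            continue
        kind = "attractive" if table.attract[types[i], types[j]] else "repulsive"
        u = pair_energy(r, kind, eps)
        if i < n_monomers:
            prof[i] += 0.5 * u
        if j < n_monomers:
            prof[j] += 0.5 * u
    mono = pos[:n_monomers]
    bonds = np.linalg.norm(np.diff(mono, axis=0), axis=1)
    for b, l in enumerate(bonds):
        e = 0.5 * kb * (l - bond_length) ** 2
        prof[b] += 0.5 * e
        prof[b + 1] += 0.5 * e
    for m in range(1, n_monomers - 1):
        b1 = mono[m] - mono[m - 1]
        b2 = mono[m + 1] - mono[m]
        ct = float(b1 @ b2) / (np.linalg.norm(b1) * np.linalg.norm(b2))
        prof[m] += kappa * (1.0 - ct)
    return prof


# --------------------------------------------------------------------------
# kymograph

def kymograph(detections: list[list[CondensateRecord]],
              n_monomers: int) -> np.ndarray:
    """(Nm, F) matrix: 1 where a monomer is inside a condensate at a frame."""
    return membership_matrix(detections, n_monomers).T.astype(np.int8)


# --------------------------------------------------------------------------
# coarsening kinetics

@dataclass
class CoarseningResult:
    series: pd.DataFrame       # time, track_id, R, R_scaled
    exponent: float | None     # growth-law exponent of the largest condensate
    exponent_stderr: float | None
    n_tracks: int
    single_droplet: bool


def coarsening_kinetics(times: np.ndarray,
                        detections: list[list[CondensateRecord]],
                        fit_lo: float = 0.2, fit_hi: float = 0.8,
                        ) -> CoarseningResult:
    """Effective radius R = (3 Vc / 4 pi)^(1/3) of tracked condensates vs
    time, scaled by the final largest radius, with a log-log growth-law fit.

    The exponent is the least-squares slope of log R vs log t over frames
    where the largest condensate's radius is between ``fit_lo`` and
    ``fit_hi`` of its final value (the growth regime, excluding the
    plateau).
    """
    times = np.asarray(times, dtype=float)
    tracks = track_condensates(detections)
    rows = []
    for tr in tracks:
        for f, rec in zip(tr.frame_indices, tr.records):
            r_eff = (3.0 * rec.volume / (4.0 * np.pi)) ** (1.0 / 3.0)
            rows.append((times[f], tr.track_id, r_eff))
    if not rows:
        return CoarseningResult(pd.DataFrame(columns=["time", "track_id", "R",
                                                      "R_scaled"]),
                                None, None, 0, True)
    df = pd.DataFrame(rows, columns=["time", "track_id", "R"])
    # largest track = the one holding the final largest radius
    final_t = df["time"].max()
    finals = df[df["time"] == final_t]
    big_id = int(finals.loc[finals["R"].idxmax(), "track_id"])
    r_final = float(finals["R"].max())
    df["R_scaled"] = df["R"] / r_final

    n_tracks = df["track_id"].nunique()
    single = n_tracks < 2
    if single:
        warnings.warn("fewer than 2 tracked condensates; "
                      "two-droplet analysis downgraded to single-droplet")

    big = df[df["track_id"] == big_id].sort_values("time")
    grow = big[(big["R"] >= fit_lo * r_final) & (big["R"] <= fit_hi * r_final)
               & (big["time"] > 0)]
    exponent = stderr = None
    if len(grow) >= 3:
        x = np.log(grow["time"].to_numpy())
        y = np.log(grow["R"].to_numpy())
        A = np.column_stack([x, np.ones_like(x)])
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        exponent = float(coef[0])
        dof = len(x) - 2
        if dof > 0 and len(res):
            s2 = float(res[0]) / dof
            stderr = float(np.sqrt(s2 / np.sum((x - x.mean()) ** 2)))
    return CoarseningResult(df, exponent, stderr, n_tracks, single)


def fit_growth_exponent(times: np.ndarray, radii: np.ndarray,
                        fit_lo: float = 0.2, fit_hi: float = 0.8) -> float:
    """Log-log least-squares exponent of a radius series (helper)."""
    times = np.asarray(times, dtype=float)
    radii = np.asarray(radii, dtype=float)
    r_final = radii[-1]
    mask = (radii >= fit_lo * r_final) & (radii <= fit_hi * r_final) & (times > 0)
    if mask.sum() < 2:
        raise ValueError("too few points in the growth window")
    x, y = np.log(times[mask]), np.log(radii[mask])
    return float(np.polyfit(x, y, 1)[0])


# --------------------------------------------------------------------------
# persistence length

@dataclass
class PersistenceResult:
    lp: float | None           # monomers (bond units)
    stderr: float | None
    unbounded: bool
    correlation: np.ndarray    # mean tangent correlation per separation
    separations: np.ndarray


def tangent_correlation(traj, max_sep: int) -> np.ndarray:
    """<t(s) . t(s + d)> averaged over contour positions and frames."""
    mono = traj.frames[:, :traj.n_monomers]
    tang = np.diff(mono, axis=1)
    tang /= np.linalg.norm(tang, axis=2, keepdims=True)
    nb = tang.shape[1]
    corr = np.empty(max_sep + 1)
    for d in range(max_sep + 1):
        dots = np.einsum("fid,fid->fi", tang[:, :nb - d], tang[:, d:])
        corr[d] = dots.mean()
    return corr


def fit_persistence_length(corr: np.ndarray,
                           seps: np.ndarray) -> PersistenceResult:
    """Fit A exp(-d / lp) to a tangent-correlation curve.

    The fit is nonlinear in correlation space, where the sampling noise is
    roughly homoscedastic; a log-linear fit would amplify the noise of the
    small long-separation correlations and is used only as the starting
    point (and fallback).  A correlation that does not decay (rigid rod)
    sets the ``unbounded`` flag instead of a value.
    """
    if np.all(corr[1:] > 0.99):
        return PersistenceResult(None, None, True, corr, seps)
    if corr[1] < np.exp(-1):
        # decorrelation within a single bond (freely-jointed limit): the
        # multi-separation fit has nothing to fit; use the first lag alone
        lp = -1.0 / np.log(corr[1]) if corr[1] > 0 else 0.5
        return PersistenceResult(float(lp), None, False, corr, seps)
    pos = (corr[1:] > 0.0)
    d = seps[1:][pos].astype(float)
    y = np.log(corr[1:][pos])
    if len(d) < 2:
        return PersistenceResult(None, None, True, corr, seps)
    A = np.column_stack([d, np.ones_like(d)])
    coef, _, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = coef[0]
    if slope >= 0:
        return PersistenceResult(None, None, True, corr, seps)
    lp0 = -1.0 / slope

    from scipy.optimize import curve_fit

    dd = seps[1:].astype(float)
    try:
        popt, pcov = curve_fit(lambda x, a, lp: a * np.exp(-x / lp),
                               dd, corr[1:], p0=(1.0, lp0),
                               bounds=((0.0, 0.1), (2.0, 1e4)))
        lp = float(popt[1])
        stderr = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else None
    except RuntimeError:
        lp, stderr = float(lp0), None
    return PersistenceResult(lp, stderr, False, corr, seps)


def persistence_length(traj_free_chain, max_sep: int = 30) -> PersistenceResult:
    """Persistence length of a free, protein-free chain trajectory.

    The long-separation correlations are dominated by slowly relaxing
    global modes, so single runs carry sizable statistical error; pooling
    :func:`tangent_correlation` curves over independent replicates and
    fitting once with :func:`fit_persistence_length` is preferred for
    quantitative estimates.
    """
    nb = traj_free_chain.n_monomers - 1
    max_sep = min(max_sep, nb - 1)
    corr = tangent_correlation(traj_free_chain, max_sep)
    return fit_persistence_length(corr, np.arange(max_sep + 1))
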