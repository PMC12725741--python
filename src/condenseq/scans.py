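"""Replicate orchestration and grid experiments (Re' scans, rho_p scans).

Every grid point runs several independently seeded replicates, each fed by
its own protein-free chain equilibration, then detection and the force /
occupancy / interfacial-affinity observables.  The desk-scale presets used
throughout shrink the chain, box and run length proportionally; see
:func:`condenseq.config.scaled_config`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .affinity import build_block_profile
from .config import ExperimentConfig, ScanSpec, scaled_config
from .detect import DetectionParams, detect_trajectory, count_equilibrium_condensates
from .engine import run_experiment
from .observables import (CoarseningResult, aggregate_forces, capillary_force,
                          coarsening_kinetics, interfacial_affinity,
                          mean_bond_length, occupancy, persistence_length)


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Distinct per-replicate seeds derived from one base seed (< 2^31)."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31 - 1)) + 1 for s in ss.spawn(n)]


def scaled_detection_params(n_monomers: int) -> DetectionParams:
    """Detection defaults adapted to desk-scale particle counts.

    Desk-scale frames are gas-dominated (a few hundred particles, most of
    them dilute), where the k-distance knee sits in the gas ramp and biases
    epsilon far above the interaction range.  The scaled experiments
    therefore cluster at a fixed epsilon of 1.5 sigma -- comfortably above
    the condensed-phase spacing (~1.1 sigma) and below the attraction
    cutoff -- and shrink the minimum condensate size with the chain.
    """
    return DetectionParams(epsilon=1.5, min_size=max(10, n_monomers // 5),
                           fallback_epsilon=1.5)


def free_chain_config(base: ExperimentConfig, seed: int | None = None,
                      production_steps: int | None = None) -> ExperimentConfig:
    """Bare untethered variant of ``base`` (reference bond length l0_bar)."""
    d = base.to_dict()
    d.update(n_proteins=0, rho_p_um=0.0)
    if seed is not None:
        d["seed"] = seed
    if production_steps is not None:
        d["production_steps"] = production_steps
        d["n_frames"] = min(base.n_frames, production_steps)
        while d["production_steps"] % d["n_frames"]:
            d["n_frames"] -= 1
    return ExperimentConfig.from_dict(d)


def run_point(config: ExperimentConfig, seeds: list[int],
              params: DetectionParams | None = None,
              traj_tethered_bare=None, traj_free_bare=None) -> dict:
    """All replicates of one grid point: simulate, detect, measure.

    Returns force aggregate, per-replicate forces and interfacial
    affinities, and equilibrium condensate counts.  Failed replicates are
    logged and excluded.
    """
    profile = build_block_profile(config.model, config.n_monomers)
    params = params or scaled_detection_params(config.n_monomers)
    if traj_tethered_bare is None:
        traj_tethered_bare = run_experiment(
            free_chain_config(config, seed=seeds[0]), profile,
            seed=seeds[0], tethered=True)
    if traj_free_bare is None:
        traj_free_bare = run_experiment(
            free_chain_config(config, seed=seeds[0]), profile,
            seed=seeds[0] + 13, tethered=False)
    forces, ias, counts, errors = [], [], [], []
    for seed in seeds:
        try:
            traj = run_experiment(config, profile, seed=seed)
            det = detect_trajectory(traj, params)
            fr = capillary_force(traj, det, traj_tethered_bare, config.kb,
                                 traj_free_bare)
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            warnings.warn(f"replicate seed={seed} failed: {exc}")
            errors.append((seed, str(exc)))
            continue
        forces.append(fr)
        try:
            occ = occupancy(det, config.n_monomers)
            ias.append(interfacial_affinity(occ, profile).ia_mean)
        except ValueError:
            ias.append(np.nan)  # no condensate wetted the chain
        half = len(det) // 2
        if len(det) - half >= 10:
            counts.append(count_equilibrium_condensates(det[half:], params))
    if not forces:
        raise RuntimeError(f"all replicates failed at this grid point: {errors}")
    out = aggregate_forces(forces)
    ia_ok = [x for x in ias if np.isfinite(x)]
    out.update({
        "forces": forces, "ia": ias, "counts": counts,
        "ia_mean": float(np.mean(ia_ok)) if ia_ok else float("nan"),
        "count_mode": int(np.bincount(counts).argmax()) if counts else 0,
        "incomplete": bool(errors), "errors": errors,
    })
    return out


def run_scan(spec: ScanSpec, seed: int = 1) -> pd.DataFrame:
    """Grid scan over Re' x rho_p with replicate aggregation."""
    rows = []
    for re_p in spec.re_prime_grid:
        base = spec.base.to_dict()
        base.update(model=spec.model, re_prime=re_p)
        free_traj = None
        teth_traj = None
        for rho in spec.rho_grid_um:
            cfg_d = dict(base)
            cfg_d.update(rho_p_um=rho, n_proteins=None)
            config = ExperimentConfig.from_dict(cfg_d)
            seeds = replicate_seeds(seed * 1000 + int(re_p * 100) * 10
                                    + int(rho), spec.replicates)
            if teth_traj is None:
                profile = build_block_profile(config.model, config.n_monomers)
                teth_traj = run_experiment(
                    free_chain_config(config, seed=seeds[0]), profile,
                    seed=seeds[0], tethered=True)
                free_traj = run_experiment(
                    free_chain_config(config, seed=seeds[0]), profile,
                    seed=seeds[0] + 13, tethered=False)
            res = run_point(config, seeds, traj_tethered_bare=teth_traj,
                            traj_free_bare=free_traj)
            rows.append({
                "model": spec.model, "re_prime": re_p, "rho_p_um": rho,
                "n_replicates": res["n_replicates"],
                "F_kBT_sigma": res["f_mean_kbt_sigma"],
                "F_std": res["f_std_kbt_sigma"],
                "F_pN": res["f_mean_pn"],
                "Ia_kBT": res["ia_mean"],
                "condensate_count": res["count_mode"],
                "incomplete": res["incomplete"],
                "config_hash": config.config_hash(),
                "seed": seed,
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# named desk-scale experiments

def persistence_length_experiment(seed: int = 1, n_monomers: int = 100,
                                  replicates: int = 10,
                                  production_steps: int = 400_000,
                                  n_frames: int = 200, max_sep: int = 30):
    """Recover lp from free, protein-free chains at default stiffness.

    Tangent correlations are pooled over independent replicate chains
    before the exponential fit: separations beyond ~lp are dominated by
    slowly relaxing global modes, so a single run's curve is too noisy for
    a quantitative estimate.
    """
    from .observables import fit_persistence_length, tangent_correlation

    config = ExperimentConfig(
        model="homogeneous", n_monomers=n_monomers, box=(80.0, 80.0, 200.0),
        re_prime=0.5, n_proteins=0, rho_p_um=0.0, dna_equil_steps=50_000,
        equil_steps=0, production_steps=production_steps, n_frames=n_frames,
        seed=seed)
    profile = build_block_profile("homogeneous", n_monomers)
    corrs = []
    for rep_seed in replicate_seeds(seed, replicates):
        cfg = ExperimentConfig.from_dict({**config.to_dict(), "seed": rep_seed})
        traj = run_experiment(cfg, profile, seed=rep_seed, tethered=False)
        corrs.append(tangent_correlation(traj, max_sep))
    corr = np.mean(corrs, axis=0)
    return fit_persistence_length(corr, np.arange(max_sep + 1))


def jump_midpoint(re_grid: np.ndarray, forces: np.ndarray) -> float:
    """Midpoint of the grid interval with the largest force increase."""
    diffs = np.diff(forces)
    i = int(np.argmax(diffs))
    return float((re_grid[i] + re_grid[i + 1]) / 2)


def het1_force_scan(seed: int = 1,
                    re_grid: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
                    replicates: int = 3, n_monomers: int = 100,
                    rho_p_um: float = 84.50, **config_overrides) -> pd.DataFrame:
    """Capillary force and interfacial affinity across an Re' grid (het1).

    The scaled chain keeps the 25%/50%/25% block proportions.  The box
    cross-section is sized so the condensate's DNA capacity at the study
    concentration is about half the contour length, matching the
    full-scale ratio that places the force switch where the interface
    crosses into the central block; half the proteins start within reach
    of the chain so nucleation does not consume the equilibration budget
    on taut chains.
    """
    profile = build_block_profile("het1", n_monomers)
    rows = []
    overrides = dict(box=(30.0, 30.0, 90.0), equil_steps=220_000,
                     production_steps=100_000, n_frames=200,
                     protein_near_chain_fraction=0.5)
    overrides.update(config_overrides)
    base = scaled_config("het1", n_monomers=n_monomers, rho_p_um=rho_p_um,
                         re_prime=0.5, seed=seed, **overrides)
    free_traj = run_experiment(free_chain_config(base, seed=seed + 13),
                               profile, seed=seed + 13, tethered=False)
    params = scaled_detection_params(n_monomers)
    for re_p in re_grid:
        cfg_d = base.to_dict()
        cfg_d["re_prime"] = re_p
        config = ExperimentConfig.from_dict(cfg_d)
        seeds = replicate_seeds(seed * 100 + int(round(re_p * 10)), replicates)
        teth = run_experiment(free_chain_config(config, seed=seeds[0]),
                              profile, seed=seeds[0], tethered=True)
        res = run_point(config, seeds, params=params,
                        traj_tethered_bare=teth, traj_free_bare=free_traj)
        rows.append({
            "re_prime": re_p, "F_kBT_sigma": res["f_mean_kbt_sigma"],
            "F_std": res["f_std_kbt_sigma"], "F_pN": res["f_mean_pn"],
            "Ia_kBT": res["ia_mean"], "n_replicates": res["n_replicates"],
        })
    out = pd.DataFrame(rows)
    out.attrs["n_monomers"] = n_monomers
    return out


def condensate_count_experiment(model: str, seed: int = 1, replicates: int = 5,
                                n_monomers: int = 50, re_prime: float = 0.6,
                                rho_p_um: float = 84.50,
                                **config_overrides) -> list[int]:
    """Equilibrium condensate counts over independent replicates."""
    profile = build_block_profile(model, n_monomers)
    params = scaled_detection_params(n_monomers)
    counts = []
    for rep_seed in replicate_seeds(seed, replicates):
        config = scaled_config(model, n_monomers=n_monomers,
                               re_prime=re_prime, rho_p_um=rho_p_um,
                               seed=rep_seed, **config_overrides)
        traj = run_experiment(config, profile, seed=rep_seed)
        det = detect_trajectory(traj, params)
        half = len(det) // 2
        counts.append(count_equilibrium_condensates(det[half:], params))
    return counts


def coarsening_run(seed: int = 1, n_monomers: int = 100,
                   re_prime: float = 0.6, rho_p_um: float = 126.75,
                   production_steps: int = 200_000,
                   n_frames: int = 2000) -> CoarseningResult:
    """Growth kinetics of one coarsening trajectory (scaled het1).

    Proteins are introduced without a separate equilibration phase so the
    production frames cover nucleation and growth from the start; frames
    are saved every tau to resolve the early growth.
    """
    profile = build_block_profile("het1", n_monomers)
    config = scaled_config("het1", n_monomers=n_monomers, re_prime=re_prime,
                           rho_p_um=rho_p_um, seed=seed, equil_steps=0,
                           production_steps=production_steps,
                           n_frames=n_frames)
    traj = run_experiment(config, profile, seed=seed)
    params = scaled_detection_params(n_monomers)
    det = detect_trajectory(traj, params)
    times = traj.times - traj.times[0] + (traj.times[1] - traj.times[0])
    return coarsening_kinetics(times, det)


def coarsening_experiment(seed: int = 1, replicates: int = 3,
                          **run_kwargs) -> CoarseningResult:
    """Ensemble growth law of the largest condensate (scaled het1).

    Individual desk-scale trajectories grow through a handful of discrete
    coalescence events, so a single largest-track radius is a staircase;
    the growth exponent is therefore fitted to the replicate-averaged
    radius curve, mirroring how multi-trajectory coarsening data are
    analyzed.
    """
    import pandas as pd

    curves, times_ref, results = [], None, []
    for rep_seed in replicate_seeds(seed, replicates):
        res = coarsening_run(seed=rep_seed, **run_kwargs)
        results.append(res)
        df = res.series
        if df.empty:
            continue
        final_t = df["time"].max()
        finals = df[df["time"] == final_t]
        tid = int(finals.loc[finals["R"].idxmax(), "track_id"])
        big = df[df["track_id"] == tid].sort_values("time")
        if times_ref is None:
            tmax = df["time"].max()
            n = len(df["time"].unique())
            times_ref = np.linspace(tmax / n, tmax, n)
        curves.append(np.interp(times_ref, big["time"], big["R"],
                                left=np.nan))
    if not curves:
        raise RuntimeError("no condensates tracked in any replicate")
    rm = np.nanmean(np.array(curves), axis=0)
    ok = ~np.isnan(rm)
    t, r = times_ref[ok], rm[ok]
    r_final = r[-max(1, len(r) // 20):].mean()
    mask = (r >= 0.2 * r_final) & (r <= 0.8 * r_final) & (t > 0)
    exponent = stderr = None
    if mask.sum() >= 3:
        x, y = np.log(t[mask]), np.log(r[mask])
        coef = np.polyfit(x, y, 1)
        exponent = float(coef[0])
        resid = y - np.polyval(coef, x)
        dof = mask.sum() - 2
        stderr = float(np.sqrt(resid.var(ddof=0) * len(x) / dof
                               / np.sum((x - x.mean()) ** 2)))
    series = pd.DataFrame({"time": t, "R": r, "R_scaled": r / r_final})
    n_tracks = max(res.n_tracks for res in results)
    return CoarseningResult(series, exponent, stderr, n_tracks,
                            n_tracks < 2)
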