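"""Trajectory and result-table I/O.

Trajectories persist as extended-XYZ text: one block per frame with the
particle count, a comment line carrying time, box, chain length, seed and
config hash, then one ``label x y z`` line per particle.  Positions are
written with 8 decimals, so a text round-trip is equal within printed
precision.  Result tables are TSV with a provenance header comment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Trajectory


class TrajectoryParseError(ValueError):
    pass


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    labels = [traj.type_labels[t] for t in traj.types]
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times):
            fh.write(f"{traj.n_particles}\n")
            box = " ".join(f"{b:g}" for b in traj.box)
            hash_ = traj.config.get("config_hash", "none")
            seed = traj.seed if traj.seed is not None else "none"
            fh.write(f'time={t:.6f} box="{box}" n_monomers={traj.n_monomers} '
                     f"seed={seed} config_hash={hash_}\n")
            for lab, (x, y, z) in zip(labels, frame):
                fh.write(f"{lab} {x:.8f} {y:.8f} {z:.8f}\n")


def _parse_comment(line: str) -> dict:
    out = {}
    i = 0
    tokens = []
    # split on spaces but keep quoted values together
    cur, in_q = "", False
    for ch in line.strip():
        if ch == '"':
            in_q = not in_q
        elif ch == " " and not in_q:
            if cur:
                tokens.append(cur)
            cur = ""
        else:
            cur += ch
    if cur:
        tokens.append(cur)
    for tok in tokens:
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_xyz(path: str | Path) -> Trajectory:
    path = Path(path)
    frames, times = [], []
    labels_first: list[str] | None = None
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"frame {frame_idx}: bad particle count line {i + 1}") from exc
        if i + 1 >= len(lines) or i + 2 + n > len(lines):
            raise TrajectoryParseError(
                f"truncated file: frame {frame_idx} incomplete; "
                f"last good frame is {frame_idx - 1}")
        meta = _parse_comment(lines[i + 1])
        pos = np.empty((n, 3))
        labels = []
        for p in range(n):
            parts = lines[i + 2 + p].split()
            if len(parts) != 4:
                raise TrajectoryParseError(
                    f"frame {frame_idx}: malformed particle line {i + 3 + p}; "
                    f"last good frame is {frame_idx - 1}")
            labels.append(parts[0])
            pos[p] = [float(v) for v in parts[1:]]
        if labels_first is None:
            labels_first = labels
        elif labels != labels_first:
            raise TrajectoryParseError(
                f"frame {frame_idx}: particle labels changed")
        frames.append(pos)
        times.append(float(meta.get("time", frame_idx)))
        i += 2 + n
        frame_idx += 1
    if not frames:
        raise TrajectoryParseError(f"no frames in {path}")
    type_labels = sorted(set(labels_first), key=labels_first.index)
    lab_to_id = {lab: t for t, lab in enumerate(type_labels)}
    types = np.array([lab_to_id[lab] for lab in labels_first])
    box = np.array([float(v) for v in meta.get("box", "0 0 0").split()])
    n_monomers = int(meta.get("n_monomers", 0))
    seed = meta.get("seed")
    seed = None if seed in (None, "none") else int(seed)
    cfg = {"config_hash": meta.get("config_hash", "none")}
    return Trajectory(np.array(frames), np.array(times), types, type_labels,
                      n_monomers, box, cfg, seed)


# --------------------------------------------------------------------------
# TSV result tables

def _write_tsv(df: pd.DataFrame, path: str | Path, provenance: dict | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            items = " ".join(f"{k}={v}" for k, v in provenance.items())
            fh.write(f"# {items}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def detection_table(detections) -> pd.DataFrame:
    rows = []
    for f, records in enumerate(detections):
        for cid, rec in enumerate(records):
            rows.append({
                "frame": f, "condensate_id": cid, "n_members": rec.size,
                "n_monomers": rec.n_monomers,
                "centroid_x": rec.centroid[0], "centroid_y": rec.centroid[1],
                "centroid_z": rec.centroid[2],
                "rx": rec.radii[0], "ry": rec.radii[1], "rz": rec.radii[2],
                "volume": rec.volume,
            })
    return pd.DataFrame(rows, columns=[
        "frame", "condensate_id", "n_members", "n_monomers", "centroid_x",
        "centroid_y", "centroid_z", "rx", "ry", "rz", "volume"])


def write_detection_tsv(detections, path, provenance=None) -> None:
    _write_tsv(detection_table(detections), path, provenance)


def write_occupancy_tsv(occ, path, provenance=None) -> None:
    _write_tsv(occ.to_frame(), path, provenance)


def write_kymograph_tsv(kymo: np.ndarray, path, provenance=None) -> None:
    df = pd.DataFrame(kymo)
    df.insert(0, "monomer", np.arange(kymo.shape[0]))
    _write_tsv(df, path, provenance)


def write_force_tsv(results: list, path, provenance=None) -> None:
    rows = [{
        "replicate": i, "F_DNA": r.f_dna, "F_DNA_protein": r.f_dna_protein,
        "F_kBT_per_sigma": r.f, "F_pN": r.f_pn, "kb": r.kb,
    } for i, r in enumerate(results)]
    _write_tsv(pd.DataFrame(rows), path, provenance)


def write_interface_tsv(result, path, provenance=None) -> None:
    rows = [{
        "core_start": s.core_span[0], "core_end": s.core_span[1],
        "side": s.side, "NmI": len(s.monomers), "Ia": s.ia,
    } for s in result.sides]
    _write_tsv(pd.DataFrame(rows), path, provenance)


def write_coarsening_tsv(result, path, provenance=None) -> None:
    _write_tsv(result.series, path, provenance)
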