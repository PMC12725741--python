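"""Synthetic frames, trajectories and bond-length series with known truth.

These generators exercise the detection and observable pipelines without
running dynamics: Gaussian particle blobs on a scattered background (with
per-particle truth labels), prescribed in/out membership patterns for the
occupancy and kymograph math, and Gaussian bond-length series with known
mean shifts for the force equations.  Everything is deterministic under its
seed.  Blob fixtures are geometric stand-ins, not physical droplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NOISE = -1


@dataclass
class FixtureSpec:
    """Blob-frame recipe: blob centers/sizes, background scatter, box."""

    blob_centers: np.ndarray                 # (nb, 3)
    blob_sizes: tuple[int, ...] = ()         # particles per blob
    blob_spreads: tuple[float, ...] = ()     # isotropic Gaussian sd, sigma
    blob_drifts: np.ndarray | None = None    # (nb, 3) per-frame displacement
    background: int = 0                      # scattered particles
    box: tuple[float, float, float] = (40.0, 40.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.blob_centers = np.atleast_2d(np.asarray(self.blob_centers, dtype=float))
        nb = len(self.blob_centers)
        if not self.blob_sizes:
            self.blob_sizes = (50,) * nb
        if not self.blob_spreads:
            self.blob_spreads = (0.5,) * nb
        if len(self.blob_sizes) != nb or len(self.blob_spreads) != nb:
            raise ValueError("per-blob sizes/spreads must match blob count")
        if any(s <= 0 for s in self.blob_spreads):
            raise ValueError("blob spreads must be positive")
        # unambiguous truth needs well-separated blobs
        for a in range(nb):
            for b in range(a + 1, nb):
                sep = np.linalg.norm(self.blob_centers[a] - self.blob_centers[b])
                lim = 5.0 * max(self.blob_spreads[a], self.blob_spreads[b])
                if sep <= lim:
                    raise ValueError(
                        f"blobs {a} and {b} separated by {sep:.2f} < 5x spread {lim:.2f}")


def make_blob_frame(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """One frame of blob + background points and its truth labels.

    Labels: blob index for members, -1 for background scatter.
    """
    rng = np.random.default_rng(spec.seed)
    pts, labels = [], []
    for b, (c, n, s) in enumerate(zip(spec.blob_centers, spec.blob_sizes,
                                      spec.blob_spreads)):
        pts.append(rng.normal(c, s, size=(n, 3)))
        labels.append(np.full(n, b))
    if spec.background:
        pts.append(rng.uniform(0, 1, size=(spec.background, 3))
                   * np.asarray(spec.box))
        labels.append(np.full(spec.background, NOISE))
    if not pts:
        return np.zeros((0, 3)), np.zeros(0, dtype=int)
    return np.vstack(pts), np.concatenate(labels).astype(int)


def make_blob_trajectory(spec: FixtureSpec, n_frames: int,
                         present: np.ndarray | None = None
                         ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Frames of drifting blobs with constant particle identity.

    ``present`` is an optional (n_frames, n_blobs) bool mask; absent blobs
    are scattered uniformly in that frame (so they cannot cluster).
    Returns (frames, per-frame truth labels).
    """
    rng = np.random.default_rng(spec.seed)
    nb = len(spec.blob_centers)
    drifts = (np.zeros((nb, 3)) if spec.blob_drifts is None
              else np.asarray(spec.blob_drifts, dtype=float))
    if present is None:
        present = np.ones((n_frames, nb), dtype=bool)
    base, labels0 = make_blob_frame(spec)
    offsets = base.copy()
    for b in range(nb):
        offsets[labels0 == b] -= spec.blob_centers[b]
    frames, truths = [], []
    for f in range(n_frames):
        pts = base.copy()
        lab = labels0.copy()
        for b in range(nb):
            sel = labels0 == b
            if present[f, b]:
                pts[sel] = offsets[sel] + spec.blob_centers[b] + f * drifts[b]
            else:
                pts[sel] = rng.uniform(0, 1, size=(sel.sum(), 3)) * np.asarray(spec.box)
                lab[sel] = NOISE
        frames.append(pts)
        truths.append(lab)
    return np.array(frames), truths


def make_membership_series(pattern: np.ndarray, omega_c: int | None = None
                           ) -> np.ndarray:
    """Membership matrix s_{m,c} (frames x monomers) from a 0/1 pattern.

    A 1-D pattern is broadcast over ``omega_c`` frames; a 2-D pattern is
    used as-is (rows = frames).
    """
    pattern = np.asarray(pattern)
    if pattern.ndim == 1:
        if omega_c is None:
            raise ValueError("omega_c required for a per-monomer pattern")
        return np.tile(pattern.astype(bool), (omega_c, 1))
    return pattern.astype(bool)


def make_bondlength_series(l0: float, shift: float, noise_sd: float,
                           n_frames: int, n_bonds: int = 499,
                           seed: int = 0) -> dict[str, np.ndarray]:
    """Paired Gaussian bond-length series for the force-pipeline oracle.

    Returns per-role (frames x bonds) arrays with prescribed means:
    ``free`` at l0, ``tethered`` at l0 + shift, ``with_protein`` at
    l0 + 2*shift (bonds outside the condensate).
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    shape = (n_frames, n_bonds)

    def series(mean: float) -> np.ndarray:
        if noise_sd:
            return mean + rng.normal(0, noise_sd, shape)
        return np.full(shape, mean)

    return {
        "free": series(l0),
        "tethered": series(l0 + shift),
        "with_protein": series(l0 + 2 * shift),
    }


def truth_to_tsv(labels: np.ndarray, path) -> None:
    pd.DataFrame({"particle": np.arange(len(labels)),
                  "blob": labels}).to_csv(path, sep="\t", index=False)


def truth_from_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["blob"].to_numpy()
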