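"""Condensate detection: DBSCAN with data-driven epsilon, and tracking.

Per frame, the DBSCAN radius epsilon is chosen from the data: sort each
particle's distance to its k-th nearest neighbor (k = MinPts - 1 = 5),
smooth the sorted curve with a Savitzky-Golay filter (degree 3, window 199),
and take the curve value at the knee -- the point of maximum discrete
curvature of the axis-normalized curve.  Clustering runs over monomers and
proteins jointly, so monomer membership is available for occupancy and
interface analysis.  Cluster extents use minimum-image coordinates relative
to a member seed, which is valid while condensates are smaller than half
the box (always the case here).

Condensate volume follows the half-max-extent ellipsoid estimate
``Vc = 4/3 pi rx ry rz`` with ``r`` half the maximum pairwise extent along
each axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

NOISE = -1


class DegenerateCurveError(ValueError):
    """The k-distance curve has no knee (e.g. a straight line)."""


@dataclass
class DetectionParams:
    min_points: int = 6
    k: int | None = None            # defaults to min_points - 1
    window: int = 199               # Savitzky-Golay window (odd)
    degree: int = 3                 # Savitzky-Golay polynomial degree
    min_size: int = 20              # discard clusters smaller than this
    persistence_fraction: float = 0.8
    epsilon: float | None = None    # fixed epsilon, skipping knee selection
    fallback_epsilon: float | None = None  # used when the knee degenerates

    def __post_init__(self) -> None:
        if self.k is None:
            self.k = self.min_points - 1
        if self.window % 2 == 0 or self.window <= self.degree:
            raise ValueError("window must be odd and larger than degree")
        if not 0 < self.persistence_fraction <= 1:
            raise ValueError("persistence_fraction must be in (0, 1]")


@dataclass
class CondensateRecord:
    members: np.ndarray          # particle indices (monomers and proteins)
    centroid: np.ndarray         # (3,), sigma
    radii: np.ndarray            # (rx, ry, rz), sigma
    volume: float                # sigma^3
    monomer_span: tuple[int, int] | None  # contour index range, or None
    frame_time: float = 0.0
    n_monomers: int = 0          # member monomers

    @property
    def size(self) -> int:
        return len(self.members)


def wrap(points: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    return points if box is None else points % np.asarray(box)


def _pairwise_pbc(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    if len(points) > 5000:
        raise ValueError("dense periodic distance matrix limited to 5000 points")
    d = points[:, None, :] - points[None, :, :]
    d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=2)


def kdistance_curve(points: np.ndarray, k: int = 5,
                    box: np.ndarray | None = None) -> np.ndarray:
    """Sorted (ascending) distance of each point to its k-th nearest neighbor."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for k={k}, got {n}")
    if box is not None:
        box = np.asarray(box, dtype=float)
        tree = cKDTree(points % box, boxsize=box)
        dists, _ = tree.query(points % box, k=k + 1)
    else:
        tree = cKDTree(points)
        dists, _ = tree.query(points, k=k + 1)
    return np.sort(dists[:, k])


def smooth_kdistance(curve: np.ndarray, window: int = 199,
                     degree: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing of the sorted k-distance curve."""
    curve = np.asarray(curve, dtype=float)
    if window % 2 == 0 or window <= degree:
        raise ValueError(f"window must be odd and > degree, got {window}/{degree}")
    if len(curve) < window:
        raise ValueError(f"curve of length {len(curve)} shorter than window {window}")
    return savgol_filter(curve, window, degree)


def knee_epsilon(smoothed: np.ndarray) -> float:
    """Curve value at the knee: the point of maximum discrete curvature.

    Both axes are normalized to [0, 1] before computing
    |y''| / (1 + y'^2)^(3/2); ties break toward the smaller index (smaller
    epsilon).  A (numerically) straight curve has no knee and raises
    :class:`DegenerateCurveError`.
    """
    y = np.asarray(smoothed, dtype=float)
    if len(y) < 5:
        raise DegenerateCurveError("curve too short for curvature estimate")
    span = y.max() - y.min()
    if span <= 0:
        raise DegenerateCurveError("constant curve has no knee")
    yn = (y - y.min()) / span
    x = np.linspace(0.0, 1.0, len(y))
    d1 = np.gradient(yn, x)
    d2 = np.gradient(d1, x)
    curvature = np.abs(d2) / (1.0 + d1 ** 2) ** 1.5
    # exclude the outermost samples: one-sided differences there produce
    # spurious curvature maxima
    margin = max(2, len(y) // 50)
    interior = curvature[margin:-margin]
    if interior.max() < 1e-4:
        raise DegenerateCurveError("curve is straight; no knee point")
    idx = margin + int(np.argmax(interior))
    return float(y[idx])


def cluster_frame(points: np.ndarray, epsilon: float, min_points: int = 6,
                  box: np.ndarray | None = None) -> np.ndarray:
    """DBSCAN labels per point (-1 = noise), deterministic in point order.

    A core point has >= ``min_points`` neighbors within ``epsilon``
    including itself (scikit-learn's convention).  With ``box`` set,
    distances are minimum-image (dense precomputed matrix).
    """
    points = np.asarray(points, dtype=float)
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if len(points) == 0:
        return np.zeros(0, dtype=int)
    if box is not None:
        dm = _pairwise_pbc(points, np.asarray(box, dtype=float))
        model = DBSCAN(eps=epsilon, min_samples=min_points, metric="precomputed")
        return model.fit_predict(dm)
    model = DBSCAN(eps=epsilon, min_samples=min_points)
    return model.fit_predict(points)


def _cluster_geometry(points: np.ndarray, box: np.ndarray | None
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Centroid, per-axis half-max-extent radii, and ellipsoid volume."""
    pts = np.asarray(points, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        rel = pts - pts[0]
        rel -= box * np.round(rel / box)
        pts = pts[0] + rel
    centroid = pts.mean(axis=0)
    radii = 0.5 * (pts.max(axis=0) - pts.min(axis=0))
    volume = 4.0 / 3.0 * np.pi * radii[0] * radii[1] * radii[2]
    if box is not None:
        centroid = centroid % box
    return centroid, radii, float(volume)


def record_from_members(points: np.ndarray, members: np.ndarray,
                        n_monomers: int = 0, frame_time: float = 0.0,
                        box: np.ndarray | None = None) -> CondensateRecord:
    members = np.asarray(members, dtype=int)
    centroid, radii, volume = _cluster_geometry(points[members], box)
    mono = members[members < n_monomers]
    span = (int(mono.min()), int(mono.max())) if len(mono) else None
    return CondensateRecord(members, centroid, radii, volume, span,
                            frame_time, len(mono))


def select_epsilon(points: np.ndarray, params: DetectionParams,
                   box: np.ndarray | None = None) -> float:
    """Epsilon via the k-distance -> smooth -> knee pipeline.

    The smoothing window is clamped to the curve length for small frames
    (the default 199 assumes full-scale particle counts); on a degenerate
    knee the configured fallback epsilon is used if present.
    """
    if params.epsilon is not None:
        return params.epsilon
    curve = kdistance_curve(points, params.k, box)
    # cap at half the curve length: a window spanning the whole curve
    # degenerates the filter to one global cubic and erases the knee
    half = max(5, len(curve) // 2)
    window = min(params.window, half if half % 2 else half - 1)
    if window > params.degree:
        curve_s = smooth_kdistance(curve, window, params.degree)
    else:
        curve_s = curve
    try:
        return knee_epsilon(curve_s)
    except DegenerateCurveError:
        if params.fallback_epsilon is not None:
            return params.fallback_epsilon
        raise


def detect_condensates(points: np.ndarray, params: DetectionParams | None = None,
                       n_monomers: int = 0, frame_time: float = 0.0,
                       box: np.ndarray | None = None) -> list[CondensateRecord]:
    """Detect condensates in one frame; returns records sorted by size."""
    params = params or DetectionParams()
    points = np.asarray(points, dtype=float)
    if len(points) < params.min_points:
        raise ValueError(
            f"frame has {len(points)} particles, fewer than MinPts={params.min_points}")
    eps = select_epsilon(points, params, box)
    labels = cluster_frame(points, eps, params.min_points, box)
    records = []
    for lab in np.unique(labels):
        if lab == NOISE:
            continue
        members = np.flatnonzero(labels == lab)
        if len(members) < params.min_size:
            continue
        records.append(record_from_members(points, members, n_monomers,
                                           frame_time, box))
    records.sort(key=lambda r: -r.size)
    return records


@dataclass
class CondensateTrack:
    """One condensate followed across frames by member overlap."""

    track_id: int
    frame_indices: list[int] = field(default_factory=list)
    records: list[CondensateRecord] = field(default_factory=list)
    members: set = field(default_factory=set)

    @property
    def n_present(self) -> int:
        return len(self.frame_indices)


def track_condensates(detections: list[list[CondensateRecord]],
                      jaccard_threshold: float = 0.3) -> list[CondensateTrack]:
    """Greedy cross-frame identity by maximum member-overlap (Jaccard).

    Frames are processed in order; each record matches the existing track
    with the highest Jaccard overlap of member sets above the threshold,
    else it opens a new track.
    """
    tracks: list[CondensateTrack] = []
    for f, records in enumerate(detections):
        claimed: set[int] = set()
        for rec in sorted(records, key=lambda r: -r.size):
            mem = set(int(i) for i in rec.members)
            best, best_j = None, jaccard_threshold
            for tr in tracks:
                if tr.track_id in claimed:
                    continue
                inter = len(mem & tr.members)
                if inter == 0:
                    continue
                j = inter / len(mem | tr.members)
                if j > best_j:
                    best, best_j = tr, j
            if best is None:
                best = CondensateTrack(track_id=len(tracks))
                tracks.append(best)
            best.frame_indices.append(f)
            best.records.append(rec)
            best.members = set(int(i) for i in rec.members)
            claimed.add(best.track_id)
    return tracks


def count_equilibrium_condensates(detections: list[list[CondensateRecord]],
                                  params: DetectionParams | None = None,
                                  ) -> int:
    """Number of condensates persisting across an equilibrium window.

    A condensate counts if its track is present in at least
    ``persistence_fraction`` of the window's frames.
    """
    params = params or DetectionParams()
    n_frames = len(detections)
    if n_frames < 10:
        raise ValueError(f"need at least 10 frames, got {n_frames}")
    tracks = track_condensates(detections)
    need = params.persistence_fraction * n_frames
    return sum(1 for tr in tracks if tr.n_present >= need)


def detect_trajectory(traj, params: DetectionParams | None = None,
                      frame_slice: slice | None = None,
                      ) -> list[list[CondensateRecord]]:
    """Run per-frame detection over a :class:`~condenseq.engine.Trajectory`.

    Epsilon is re-selected for every frame.  Frames too dilute to cluster
    (degenerate knee without fallback) yield an empty record list.
    """
    params = params or DetectionParams()
    out: list[list[CondensateRecord]] = []
    frames = traj.frames if frame_slice is None else traj.frames[frame_slice]
    times = traj.times if frame_slice is None else traj.times[frame_slice]
    for pts, t in zip(frames, times):
        try:
            out.append(detect_condensates(pts, params, traj.n_monomers,
                                          float(t), traj.box))
        except DegenerateCurveError:
            out.append([])
    return out
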