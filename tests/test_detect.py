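import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condenseq.detect import (CondensateRecord, DegenerateCurveError,
                              DetectionParams, cluster_frame,
                              count_equilibrium_condensates,
                              detect_condensates, kdistance_curve,
                              knee_epsilon, record_from_members,
                              smooth_kdistance, track_condensates)
from condenseq.fixtures import FixtureSpec, make_blob_frame, make_blob_trajectory


# --------------------------------------------------------------------------
# independent oracles

def brute_force_kdist(points, k):
    """k-th nearest neighbor distance per point by full sort."""
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    d.sort(axis=1)
    return np.sort(d[:, k])


def dbscan_oracle(points, eps, min_pts):
    """DBSCAN by definition: epsilon-graph connected components over core
    points, border points attached to any adjacent core's cluster.

    Returns (labels_for_cores, core_mask, border_clusters) where
    ``border_clusters[i]`` is the set of admissible cluster ids for border
    point i (border assignment is order-dependent in DBSCAN proper).
    """
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts  # includes self
    labels = np.full(n, -1)
    cid = 0
    for s in range(n):
        if core[s] and labels[s] == -1:
            stack = [s]
            labels[s] = cid
            while stack:
                u = stack.pop()
                for v in np.flatnonzero(neigh[u] & core):
                    if labels[v] == -1:
                        labels[v] = cid
                        stack.append(v)
            cid += 1
    border_options = {}
    for i in range(n):
        if not core[i]:
            opts = {labels[j] for j in np.flatnonzero(neigh[i] & core)}
            border_options[i] = opts
    return labels, core, border_options


def assert_matches_oracle(points, eps, min_pts):
    got = cluster_frame(points, eps, min_pts)
    labels, core, border_options = dbscan_oracle(points, eps, min_pts)
    # cores: identical partition up to label permutation
    mapping = {}
    for i in np.flatnonzero(core):
        assert got[i] != -1
        key = labels[i]
        if key in mapping:
            assert mapping[key] == got[i]
        else:
            assert got[i] not in mapping.values()
            mapping[key] = got[i]
    # non-cores: noise iff no adjacent core; else assigned to an adjacent
    # core's cluster
    for i, opts in border_options.items():
        if not opts:
            assert got[i] == -1
        else:
            assert got[i] in {mapping[o] for o in opts}


# --------------------------------------------------------------------------

class TestKDistance:
    def test_coincident_points_all_zero(self):
        pts = np.zeros((10, 3))
        assert np.all(kdistance_curve(pts, 5) == 0.0)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 10, (rng.integers(20, 100), 3))
            for k in (1, 3, 5):
                assert np.allclose(kdistance_curve(pts, k),
                                   brute_force_kdist(pts, k))

    def test_two_separated_blobs_have_no_gap_values(self, rng):
        a = rng.normal(0, 0.3, (30, 3))
        b = rng.normal(0, 0.3, (30, 3)) + [20.0, 0, 0]
        curve = kdistance_curve(np.vstack([a, b]), 5)
        assert curve.max() < 3.0  # every 5-NN stays within its blob

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kdistance_curve(np.zeros((4, 3)), 5)

    def test_periodic_wraps_distances(self):
        box = np.array([10.0, 10.0, 10.0])
        pts = np.zeros((8, 3))
        pts[:4, 0] = [0.2, 0.4, 0.6, 0.8]
        pts[4:, 0] = [9.2, 9.4, 9.6, 9.8]   # adjacent across the boundary
        curve = kdistance_curve(pts, 3, box)
        assert curve.max() < 2.0


class TestSavGol:
    def test_reproduces_cubic_exactly(self):
        x = np.linspace(0, 1, 301)
        y = 2.0 + 0.5 * x - 1.2 * x ** 2 + 3.1 * x ** 3
        assert np.allclose(smooth_kdistance(y, 99, 3), y, atol=1e-10)

    def test_constant_unchanged(self):
        y = np.full(250, 1.7)
        assert np.allclose(smooth_kdistance(y, 199, 3), y)

    def test_noisy_ramp_keeps_slope(self, rng):
        x = np.arange(500.0)
        y = x + rng.normal(0, 5.0, 500)
        sm = smooth_kdistance(y, 99, 3)
        slope = np.polyfit(x[60:-60], sm[60:-60], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("window,degree", [(100, 3), (5, 7), (3, 3)])
    def test_parameter_validation(self, window, degree):
        with pytest.raises(ValueError):
            smooth_kdistance(np.arange(300.0), window, degree)

    def test_curve_shorter_than_window(self):
        with pytest.raises(ValueError, match="shorter"):
            smooth_kdistance(np.arange(50.0), 99, 3)


class TestKnee:
    def test_flat_then_ramp_knee_at_joint(self):
        # analytic curve: 80% flat at 0.1, then linear ramp to 5.0; the
        # only curvature is at the joint, so epsilon ~ 0.1
        n = 1000
        y = np.concatenate([np.full(800, 0.1),
                            np.linspace(0.1, 5.0, 200)])
        eps = knee_epsilon(y)
        assert 0.05 <= eps <= 0.35

    def test_straight_line_raises(self):
        with pytest.raises(DegenerateCurveError):
            knee_epsilon(np.linspace(0.0, 5.0, 500))

    def test_constant_curve_raises(self):
        with pytest.raises(DegenerateCurveError):
            knee_epsilon(np.full(100, 2.0))

    def test_tie_breaks_toward_smaller_epsilon(self):
        # symmetric double corner: down-up staircase; first corner wins
        y = np.concatenate([np.full(100, 1.0), np.linspace(1, 2, 100),
                            np.full(100, 2.0)])
        eps = knee_epsilon(y)
        assert eps < 1.5


class TestDBSCAN:
    def test_two_blobs_two_clusters_no_noise(self, rng):
        a = rng.normal(0, 0.5, (50, 3))
        b = rng.normal(0, 0.5, (50, 3)) + [20.0, 0, 0]
        labels = cluster_frame(np.vstack([a, b]), 1.0, 6)
        assert set(labels[labels >= 0]) == {0, 1}
        assert np.sum(labels == -1) <= 2  # at most a couple of tail outliers
        # each blob maps onto a single distinct cluster
        assert len(set(labels[:50][labels[:50] >= 0])) == 1
        assert len(set(labels[50:][labels[50:] >= 0])) == 1
        assert labels[0] != labels[99]

    def test_isolated_points_all_noise(self):
        pts = np.arange(10)[:, None] * np.array([5.0, 0, 0])
        labels = cluster_frame(pts, 1.0, 6)
        assert np.all(labels == -1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(20, 200),
           st.sampled_from([0.6, 1.0, 1.6]), st.sampled_from([4, 6, 8]))
    def test_equals_brute_force_oracle(self, seed, n, eps, min_pts):
        rng = np.random.default_rng(seed)
        # mixture of a couple of dense patches plus scatter
        pts = np.vstack([
            rng.normal(rng.uniform(0, 10, 3), 0.5, (n // 3, 3)),
            rng.normal(rng.uniform(0, 10, 3), 0.5, (n // 3, 3)),
            rng.uniform(0, 10, (n - 2 * (n // 3), 3)),
        ])
        assert_matches_oracle(pts, eps, min_pts)

    def test_periodic_metric_joins_across_boundary(self, rng):
        box = np.array([10.0, 40.0, 40.0])
        blob = rng.normal(0, 0.4, (30, 3)) + [0.0, 20.0, 20.0]
        blob[:, 0] %= 10.0  # half the blob wraps to x ~ 9.x
        labels = cluster_frame(blob, 1.5, 6, box)
        assert len(set(labels)) == 1 and -1 not in set(labels)


class TestDetectCondensates:
    def test_recovers_implanted_blob(self, rng):
        spec = FixtureSpec(blob_centers=[[20.0, 20.0, 20.0]],
                           blob_sizes=(120,), blob_spreads=(0.6,),
                           background=500, box=(60.0, 60.0, 60.0), seed=3)
        frame, truth = make_blob_frame(spec)
        records = detect_condensates(frame, DetectionParams())
        assert len(records) >= 1
        members = set(records[0].members)
        implanted = set(np.flatnonzero(truth == 0))
        assert len(members & implanted) / len(implanted) >= 0.95

    def test_dilute_frame_returns_nothing(self, rng):
        # all points isolated at the clustering radius -> no records
        pts = rng.uniform(0, 100, (120, 3))  # ~1 point per 8000 sigma^3
        params = DetectionParams(epsilon=1.5, min_size=20)
        assert detect_condensates(pts, params) == []

    def test_volume_formula(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, -1, 0], [1.0, 1, 0],
                        [1.0, 0, -1], [1.0, 0, 1]])
        rec = record_from_members(pts, np.arange(6))
        assert rec.radii == pytest.approx([1.0, 1.0, 1.0])
        assert rec.volume == pytest.approx(4.18879, abs=1e-4)
        assert rec.volume == pytest.approx(4 / 3 * np.pi
                                           * np.prod(rec.radii))

    def test_reordering_invariance(self, rng):
        spec = FixtureSpec(blob_centers=[[10.0, 10, 10], [10.0, 10, 40]],
                           blob_sizes=(40, 40), blob_spreads=(0.5, 0.5),
                           background=60, box=(20.0, 20.0, 50.0), seed=5)
        frame, _ = make_blob_frame(spec)
        params = DetectionParams(min_size=20, fallback_epsilon=1.5)
        rec1 = detect_condensates(frame, params)
        perm = rng.permutation(len(frame))
        rec2 = detect_condensates(frame[perm], params)
        sets1 = {frozenset(int(i) for i in r.members) for r in rec1}
        sets2 = {frozenset(int(i) for i in perm[r.members]) for r in rec2}
        assert sets1 == sets2

    def test_sphere_volume_estimator_consistency(self, rng):
        # half-max-extent radii of points filling a sphere converge on the
        # true sphere volume
        r = 3.0
        pts = rng.normal(0, 1, (8000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= r * rng.uniform(0, 1, (8000, 1)) ** (1 / 3)
        rec = record_from_members(pts, np.arange(len(pts)))
        assert rec.volume == pytest.approx(4 / 3 * np.pi * r ** 3, rel=0.05)

    def test_min_points_precondition(self):
        with pytest.raises(ValueError):
            detect_condensates(np.zeros((3, 3)), DetectionParams())


class TestTrackingAndCounting:
    def _detections_from_traj(self, frames, truths):
        out = []
        for frame, truth in zip(frames, truths):
            recs = []
            for b in set(truth[truth >= 0]):
                recs.append(record_from_members(frame,
                                                np.flatnonzero(truth == b)))
            out.append(recs)
        return out

    def test_two_stationary_blobs_count_two(self):
        spec = FixtureSpec(blob_centers=[[10.0, 10, 10], [10.0, 10, 40]],
                           blob_sizes=(40, 40), blob_spreads=(0.5, 0.5),
                           box=(20.0, 20.0, 50.0), seed=1)
        frames, truths = make_blob_trajectory(spec, 20)
        det = self._detections_from_traj(frames, truths)
        assert count_equilibrium_condensates(det, DetectionParams()) == 2

    def test_intermittent_blob_not_counted(self):
        spec = FixtureSpec(blob_centers=[[10.0, 10, 10], [10.0, 10, 40]],
                           blob_sizes=(40, 40), blob_spreads=(0.5, 0.5),
                           box=(20.0, 20.0, 50.0), seed=2)
        present = np.ones((20, 2), dtype=bool)
        present[6:, 1] = False  # second blob in only 30% of frames
        frames, truths = make_blob_trajectory(spec, 20, present=present)
        det = self._detections_from_traj(frames, truths)
        params = DetectionParams(persistence_fraction=0.8)
        assert count_equilibrium_condensates(det, params) == 1

    def test_drifting_blob_keeps_identity(self):
        spec = FixtureSpec(blob_centers=[[10.0, 10, 10]], blob_sizes=(50,),
                           blob_spreads=(0.5,), blob_drifts=[[0.0, 0, 0.8]],
                           box=(20.0, 20.0, 60.0), seed=3)
        frames, truths = make_blob_trajectory(spec, 15)
        det = self._detections_from_traj(frames, truths)
        tracks = track_condensates(det)
        assert len(tracks) == 1
        assert tracks[0].n_present == 15

    def test_needs_ten_frames(self):
        with pytest.raises(ValueError):
            count_equilibrium_condensates([[]] * 5, DetectionParams())
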