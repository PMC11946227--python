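import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cowgait import (
    AngleSeries,
    InsufficientDataError,
    clean_trajectory,
    compute_angle_series,
    keypoint_distance,
    summarize_angles,
    vertex_angle,
)
from cowgait.keypoint_io import KEYPOINTS


def dot_product_angle(vertex, end1, end2):
    """Independent oracle: angle between the two vertex-to-endpoint vectors."""
    u = np.asarray(end1, float) - np.asarray(vertex, float)
    v = np.asarray(end2, float) - np.asarray(vertex, float)
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(cos, -1, 1)))


finite_coord = st.floats(-1e3, 1e3)
point = st.tuples(finite_coord, finite_coord)


class TestKeypointDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((0, 0), (3, 4), 5.0), ((7, -2), (7, -2), 0.0), ((1, 2), (4, 6), 5.0)],
    )
    def test_known_distances(self, a, b, expected):
        assert keypoint_distance(a, b) == pytest.approx(expected)
        assert keypoint_distance(b, a) == pytest.approx(expected)

    def test_missing_coordinate_gives_nan(self):
        assert np.isnan(keypoint_distance((np.nan, 0), (1, 1)))


class TestVertexAngle:
    @pytest.mark.parametrize(
        "vertex,e1,e2,expected",
        [
            ((1, 0), (0, 0), (2, 0), 180.0),
            ((0, 1), (0, 0), (1, 1), 90.0),
            # isoceles 5-5-6: arccos(14/50) in degrees
            ((3, 4), (0, 0), (6, 0), np.degrees(np.arccos(14 / 50))),
        ],
    )
    def test_known_angles(self, vertex, e1, e2, expected):
        assert vertex_angle(vertex, e1, e2) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_triangle_is_missing(self):
        assert np.isnan(vertex_angle((0, 0), (0, 0), (1, 1)))

    def test_agrees_with_dot_product_oracle_on_random_triangles(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 1000:
            pts = rng.uniform(-500, 500, (3, 2))
            sides = [np.linalg.norm(pts[i] - pts[(i + 1) % 3]) for i in range(3)]
            if min(sides) < 1e-3:
                continue
            got = vertex_angle(pts[0], pts[1], pts[2])
            want = dot_product_angle(pts[0], pts[1], pts[2])
            assert got == pytest.approx(want, abs=1e-9)
            checked += 1

    def test_triangle_angles_sum_to_180(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            a, b, c = rng.uniform(-100, 100, (3, 2))
            if min(
                np.linalg.norm(a - b), np.linalg.norm(b - c), np.linalg.norm(a - c)
            ) < 1e-2:
                continue
            total = (
                vertex_angle(a, b, c) + vertex_angle(b, a, c) + vertex_angle(c, a, b)
            )
            assert total == pytest.approx(180.0, abs=1e-6)

    @settings(max_examples=150, derandomize=True)
    @given(
        pts=st.tuples(point, point, point),
        angle=st.floats(-np.pi, np.pi),
        scale=st.floats(0.01, 100),
        shift=point,
        reflect=st.booleans(),
    )
    def test_similarity_invariance(self, pts, angle, scale, shift, reflect):
        """Angles are unchanged by translation, rotation, reflection, scaling."""
        pts = np.array(pts, float)
        sides = [np.linalg.norm(pts[i] - pts[(i + 1) % 3]) for i in range(3)]
        u, w = pts[1] - pts[0], pts[2] - pts[0]
        area2 = abs(u[0] * w[1] - u[1] * w[0])
        if min(sides) < 1e-3 or area2 / max(sides) ** 2 < 1e-3:
            return  # near-degenerate triangles are numerically ill-posed
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        if reflect:
            rot = rot @ np.diag([1.0, -1.0])
        moved = scale * pts @ rot.T + np.asarray(shift)
        before = vertex_angle(pts[0], pts[1], pts[2])
        after = vertex_angle(moved[0], moved[1], moved[2])
        assert after == pytest.approx(before, abs=1e-9)


class TestCleanTrajectory:
    def test_all_good_frames_is_identity(self, make_bout):
        bout = make_bout(n=10)
        assert clean_trajectory(bout) == bout

    def test_single_bad_frame_interpolated_at_midpoint(self, make_bout):
        bout = make_bout(n=3)
        bout.data.loc[0, ("K1", "x")] = 10.0
        bout.data.loc[1, ("K1", "x")] = 999.0
        bout.data.loc[2, ("K1", "x")] = 12.0
        bout.data.loc[1, ("K1", "likelihood")] = 0.1
        cleaned = clean_trajectory(bout, likelihood_threshold=0.6)
        assert cleaned.data.loc[1, ("K1", "x")] == pytest.approx(11.0)

    def test_gap_longer_than_max_gap_stays_missing(self, make_bout):
        max_gap = 3
        bout = make_bout(n=max_gap + 3)
        bad = list(range(1, 1 + max_gap + 1))  # max_gap + 1 consecutive bad frames
        for i in bad:
            bout.data.loc[i, ("K2", "likelihood")] = 0.0
        cleaned = clean_trajectory(bout, max_gap=max_gap)
        assert np.isnan(cleaned.data.loc[bad, ("K2", "x")]).all()
        # the same gap one frame shorter is bridged
        bout2 = make_bout(n=max_gap + 3)
        for i in bad[:-1]:
            bout2.data.loc[i, ("K2", "likelihood")] = 0.0
        cleaned2 = clean_trajectory(bout2, max_gap=max_gap)
        assert np.isfinite(cleaned2.data[("K2", "x")]).all()

    def test_endpoints_never_extrapolated(self, make_bout):
        bout = make_bout(n=5)
        bout.data.loc[0, ("K4", "likelihood")] = 0.0
        bout.data.loc[4, ("K4", "likelihood")] = 0.0
        cleaned = clean_trajectory(bout)
        assert np.isnan(cleaned.data.loc[0, ("K4", "x")])
        assert np.isnan(cleaned.data.loc[4, ("K4", "x")])
        assert cleaned.data.loc[0, ("K4", "likelihood")] == 0.0


class TestComputeAngleSeries:
    def test_collinear_keypoints_give_180(self, make_bout):
        series = compute_angle_series(make_bout(n=5))
        assert np.allclose(series.alpha, 180.0)
        assert np.allclose(series.beta, 180.0)

    def test_missing_k1_drops_alpha_only(self, make_bout):
        bout = make_bout(n=5)
        bout.data.loc[2, ("K1", "x")] = np.nan
        bout.data.loc[2, ("K1", "y")] = np.nan
        series = compute_angle_series(bout)
        assert np.isnan(series.alpha[2])
        assert np.isfinite(series.beta[2])
        assert np.isfinite(series.alpha[[0, 1, 3, 4]]).all()


class TestSummarizeAngles:
    def _series(self, alpha, beta=None):
        alpha = np.asarray(alpha, float)
        beta = alpha if beta is None else np.asarray(beta, float)
        return AngleSeries("s", 25.0, np.arange(len(alpha)), alpha, beta)

    def test_normal_alpha_interval_reproduces_amplitude(self):
        s = self._series([146.26, 150.0, 164.87])
        out = summarize_angles(s, min_valid_frames=1)
        assert out.alpha.interval_low == pytest.approx(146.26)
        assert out.alpha.interval_high == pytest.approx(164.87)
        assert out.alpha.amplitude == pytest.approx(18.61)

    def test_mild_beta_amplitude(self):
        s = self._series([150.0], None)
        s = self._series([150.0, 160.0], [173.53, 179.93])
        out = summarize_angles(s, min_valid_frames=1)
        assert out.beta.amplitude == pytest.approx(6.40)

    def test_constant_series_zero_amplitude(self):
        s = self._series([155.0] * 60)
        out = summarize_angles(s)
        assert out.alpha.amplitude == 0.0
        assert out.alpha.interval_low == out.alpha.mean == out.alpha.interval_high

    def test_minmax_amplitude_is_exact_range(self, rng):
        vals = rng.uniform(140, 170, 80)
        out = summarize_angles(self._series(vals))
        assert out.alpha.amplitude == vals.max() - vals.min()

    def test_percentile_interval_is_narrower(self, rng):
        vals = rng.uniform(140, 170, 500)
        mm = summarize_angles(self._series(vals), interval_method="minmax")
        pc = summarize_angles(
            self._series(vals), interval_method="percentile", percentile_tail=5.0
        )
        assert pc.alpha.interval_low > mm.alpha.interval_low
        assert pc.alpha.interval_high < mm.alpha.interval_high

    def test_too_few_frames_names_angle(self):
        alpha = np.full(60, np.nan)
        alpha[:10] = 150.0
        s = self._series(alpha, np.full(60, 178.0))
        with pytest.raises(InsufficientDataError, match="alpha"):
            summarize_angles(s)


class TestInvariances:
    def test_similarity_transform_leaves_series_unchanged(self, make_bout, rng):
        from cowgait.keypoint_io import bout_from_arrays
        from cowgait.synthetic import GaitSimConfig, simulate_bout

        bout = simulate_bout(GaitSimConfig.for_grade(2, seed=5))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        coords = {kp: 3.5 * bout.xy(kp) @ rot.T + np.array([40.0, -7.0]) for kp in KEYPOINTS}
        moved = bout_from_arrays("moved", bout.fps, coords)
        a = compute_angle_series(bout)
        b = compute_angle_series(moved)
        assert np.allclose(a.alpha, b.alpha, atol=1e-9)
        assert np.allclose(a.beta, b.beta, atol=1e-9)
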