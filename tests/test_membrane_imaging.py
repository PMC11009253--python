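"""Arc detection, continuity filtering, and circle-fit correctness."""

import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from patchtension.errors import (
    DegenerateGeometryError,
    InsufficientPointsError,
    InvalidArgumentError,
    OutOfRangeError,
)
from patchtension.membrane_imaging import (
    CircleFit,
    ImageStack,
    MembranePointSet,
    detect_membrane_points,
    enforce_continuity,
    fit_circle_algebraic,
    fit_circle_three_point,
    frame_index_for_time,
    radius_physical,
)


def circle_points(cx, cy, r, angles):
    a = np.asarray(angles, dtype=float)
    return np.column_stack([cx + r * np.cos(a), cy + r * np.sin(a)])


def make_stack(n=10, rate=120.0):
    return ImageStack(frames=np.zeros((n, 4, 4)), frame_rate=rate, pixel_scale=0.05)


class TestFrameTimeMatching:
    @pytest.mark.parametrize(
        "t,expected",
        [(0.0, 0), (0.5, 60), (1.0, 119)],  # t == duration clamps to last frame
    )
    def test_index_is_floor_of_rate_times_time(self, t, expected):
        stack = make_stack(n=120, rate=120.0)
        assert frame_index_for_time(stack, t) == expected

    @pytest.mark.parametrize("t", [-0.1, 2.0, float("nan")])
    def test_out_of_range_times_rejected(self, t):
        with pytest.raises(OutOfRangeError):
            frame_index_for_time(make_stack(n=120), t)


class TestDetection:
    def test_synthetic_arc_detected_exactly(self):
        # one bright pixel per row on an analytic arc, dark elsewhere
        frame = np.zeros((20, 40))
        true_cols = [int(10 + math.sqrt(81 - (row - 10) ** 2)) for row in range(3, 18)]
        for row, col in zip(range(3, 18), true_cols):
            frame[row, col] = 100.0
        pts = detect_membrane_points(frame, (3, 18, 0, 40), subpixel=False)
        assert np.array_equal(pts.cols, np.array(true_cols, dtype=float))

    def test_uniform_frame_ties_break_leftmost(self):
        pts = detect_membrane_points(np.ones((5, 9)), (0, 5, 2, 9), subpixel=False)
        assert np.all(pts.cols == 2.0)

    def test_single_row_roi(self):
        frame = np.zeros((5, 9))
        frame[2, 6] = 1.0
        pts = detect_membrane_points(frame, (2, 3, 0, 9))
        assert pts.n_points == 1
        assert pts.cols[0] == 6.0

    def test_empty_roi_rejected(self):
        with pytest.raises(InvalidArgumentError):
            detect_membrane_points(np.zeros((5, 5)), (3, 3, 0, 5))

    def test_subpixel_refinement_recovers_gaussian_center(self):
        # Gaussian profile centered at a fractional column
        frame = np.zeros((3, 21))
        cols = np.arange(21)
        frame[1] = 50.0 * np.exp(-((cols - 10.3) ** 2) / (2 * 1.2**2))
        pts = detect_membrane_points(frame, (1, 2, 0, 21), subpixel=True)
        assert pts.cols[0] == pytest.approx(10.3, abs=1e-6)


class TestThreePointFit:
    @pytest.mark.parametrize(
        "pts,center,radius",
        [
            ([(0, 1), (1, 0), (0, -1)], (0.0, 0.0), 1.0),
            ([(0, 0), (2, 0), (1, 1)], (1.0, 0.0), 1.0),
        ],
    )
    def test_hand_checkable_circles(self, pts, center, radius):
        fit = fit_circle_three_point(*pts)
        assert fit.center == pytest.approx(center)
        assert fit.radius_px == pytest.approx(radius)
        assert fit.rms_residual_px == 0.0

    def test_collinear_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            fit_circle_three_point((0, 0), (1, 1), (2, 2))

    def test_duplicate_points_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_circle_three_point((0, 0), (0, 0), (1, 1))


class TestAlgebraicFit:
    def test_exact_circle_recovered(self):
        pts = circle_points(10, 20, 7, np.linspace(0, 2 * np.pi, 50, endpoint=False))
        fit = fit_circle_algebraic(pts)
        assert fit.center == pytest.approx((10, 20), abs=1e-9)
        assert fit.radius_px == pytest.approx(7, abs=1e-9)
        assert fit.rms_residual_px < 1e-9

    def test_collinear_degenerate(self):
        pts = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        with pytest.raises(DegenerateGeometryError):
            fit_circle_algebraic(pts)

    @given(
        st.tuples(
            st.floats(-20, 20), st.floats(-20, 20), st.floats(-20, 20),
            st.floats(-20, 20), st.floats(-20, 20), st.floats(-20, 20),
        )
    )
    def test_three_point_equivalence_with_algebraic(self, coords):
        """On any 3 non-collinear points the two fit routes agree to 1e-9 px."""
        x1, y1, x2, y2, x3, y3 = coords
        p = [(x1, y1), (x2, y2), (x3, y3)]
        area2 = abs(
            (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
        )
        assume(area2 > 1.0)  # robustly non-collinear
        direct = fit_circle_three_point(*p)
        assume(direct.radius_px < 1e4)
        alg = fit_circle_algebraic(np.asarray(p, dtype=float))
        assert alg.radius_px == pytest.approx(direct.radius_px, abs=1e-9, rel=1e-9)
        assert alg.center[0] == pytest.approx(direct.center[0], abs=1e-9, rel=1e-9)
        assert alg.center[1] == pytest.approx(direct.center[1], abs=1e-9, rel=1e-9)

    @given(
        angle=st.floats(0, 2 * math.pi),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
    )
    def test_rotation_translation_equivariance(self, angle, dx, dy):
        rng = np.random.default_rng(0)
        pts = circle_points(2.0, -1.0, 5.0, np.linspace(0.3, 2.5, 25))
        pts = pts + rng.normal(scale=0.3, size=pts.shape)  # fixed noisy arc
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        moved = pts @ rot.T + np.array([dx, dy])
        f0 = fit_circle_algebraic(pts)
        f1 = fit_circle_algebraic(moved)
        assert f1.radius_px == pytest.approx(f0.radius_px, abs=1e-9, rel=1e-9)
        c0 = rot @ np.array(f0.center) + np.array([dx, dy])
        assert f1.center[0] == pytest.approx(c0[0], abs=1e-8)
        assert f1.center[1] == pytest.approx(c0[1], abs=1e-8)

    @given(off=st.floats(1.0, 30.0), angle=st.floats(0, 2 * math.pi))
    def test_adding_off_circle_point_increases_rms(self, off, angle):
        pts = circle_points(0, 0, 10, np.linspace(0, 2 * np.pi, 30, endpoint=False))
        base = fit_circle_algebraic(pts)
        outlier = np.array([[(10 + off) * math.cos(angle), (10 + off) * math.sin(angle)]])
        grown = fit_circle_algebraic(np.vstack([pts, outlier]))
        assert grown.rms_residual_px >= base.rms_residual_px

    def test_noisy_arc_radius_recovery_within_one_pixel(self):
        """200-point arcs of an 80 px circle with 0.5 px noise: mean radius
        error under 1 px across 100 seeded replicates."""
        angles = np.linspace(-np.pi / 3, np.pi / 3, 200)
        errs_kasa, errs_geo = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = circle_points(0, 0, 80, angles) + rng.normal(scale=0.5, size=(200, 2))
            errs_kasa.append(fit_circle_algebraic(pts).radius_px - 80.0)
            errs_geo.append(fit_circle_algebraic(pts, refine=True).radius_px - 80.0)
        assert abs(np.mean(errs_kasa)) < 1.0
        assert abs(np.mean(errs_geo)) < 1.0

    def test_matches_independent_total_least_squares_oracle(self):
        skimage_measure = pytest.importorskip("skimage.measure")
        rng = np.random.default_rng(3)
        pts = circle_points(5, -3, 40, np.linspace(0, 2 * np.pi, 120, endpoint=False))
        pts = pts + rng.normal(scale=0.4, size=pts.shape)
        fit = fit_circle_algebraic(pts, refine=True)
        if hasattr(skimage_measure.CircleModel, "from_estimate"):
            model = skimage_measure.CircleModel.from_estimate(pts)
            r_oracle = model.radius
        else:  # older scikit-image
            model = skimage_measure.CircleModel()
            assert model.estimate(pts)
            r_oracle = model.params[2]
        assert fit.radius_px == pytest.approx(r_oracle, abs=0.05)


class TestContinuityFilters:
    @staticmethod
    def arc_point_set(n=40, outliers=None):
        rows = np.arange(n, dtype=float)
        cols = 20.0 + np.sqrt(60.0**2 - (rows - n / 2) ** 2)
        for r, delta in (outliers or {}).items():
            cols[r] += delta
        return MembranePointSet(rows=rows, cols=cols, intensities=np.full(n, 100.0))

    @pytest.mark.parametrize("method", ["max_jump", "median_residual", "ransac_circle"])
    def test_clean_arc_fully_retained(self, method):
        pts = self.arc_point_set()
        kept = enforce_continuity(pts, method)
        assert kept.n_points == pts.n_points

    def test_ransac_removes_implanted_outliers_only(self):
        outliers = {3: 25.0, 11: -22.0, 19: 30.0, 27: 20.0, 35: -25.0}
        pts = self.arc_point_set(outliers=outliers)
        kept = enforce_continuity(pts, "ransac_circle", ransac_tol_px=2.0, seed=0)
        assert kept.n_points == pts.n_points - len(outliers)
        assert not set(outliers) & set(kept.rows.astype(int))

    def test_median_residual_removes_implanted_outliers(self):
        pts = self.arc_point_set(outliers={5: -25.0, 20: 25.0})
        kept = enforce_continuity(pts, "median_residual", residual_c=3.0)
        assert not {5, 20} & set(kept.rows.astype(int))

    def test_max_jump_removes_column_jumps(self):
        pts = self.arc_point_set(outliers={10: 25.0})
        kept = enforce_continuity(pts, "max_jump", max_jump_px=5.0)
        assert 10 not in kept.rows.astype(int)

    def test_collinear_points_have_no_circle_consensus(self):
        pts = MembranePointSet(
            rows=np.arange(10.0), cols=np.full(10, 7.0), intensities=np.ones(10)
        )
        with pytest.raises(InsufficientPointsError):
            enforce_continuity(pts, "ransac_circle")

    def test_too_few_points_rejected(self):
        pts = MembranePointSet(rows=[0.0, 1.0], cols=[0.0, 1.0], intensities=[1, 1])
        with pytest.raises(InsufficientPointsError):
            enforce_continuity(pts, "max_jump")


class TestPhysicalRadius:
    def test_pixel_scale_product(self):
        fit = CircleFit(center=(0, 0), radius_px=100.0, rms_residual_px=0.0,
                        n_points=3, method="three_point")
        assert radius_physical(fit, 0.05) == pytest.approx(5.0)
        assert radius_physical(fit, 0.036) == pytest.approx(3.6, abs=1e-12)

    def test_nonpositive_scale_rejected(self):
        fit = CircleFit(center=(0, 0), radius_px=1.0, rms_residual_px=0.0,
                        n_points=3, method="three_point")
        with pytest.raises(InvalidArgumentError):
            radius_physical(fit, 0.0)
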