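import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pterygrade import (
    CORNEA,
    DegenerateGeometryError,
    EmptyClassError,
    WeightCollapseError,
    WeightFunctionSpec,
    extract_class_contour,
    fit_circle_algebraic,
    fit_circle_irls,
    weight_value,
)
from conftest import circle_points, occluded_circle_points


class TestContourExtraction:
    def test_filled_square_has_perimeter_boundary(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:15, 5:15] = CORNEA
        contour = extract_class_contour(mask, CORNEA)
        assert len(contour) == 36  # 10*4 - 4 corner double counts
        # brute-force oracle: region pixels with an 8-neighbour outside
        expected = set()
        for y in range(5, 15):
            for x in range(5, 15):
                neighbours = [(y + dy, x + dx) for dy in (-1, 0, 1)
                              for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
                if any(not (5 <= ny < 15 and 5 <= nx < 15)
                       for ny, nx in neighbours):
                    expected.add((x, y))
        assert {tuple(map(int, p)) for p in contour.points} == expected

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 3] = CORNEA
        contour = extract_class_contour(mask, CORNEA)
        assert contour.points.tolist() == [[3.0, 2.0]]

    def test_trace_starts_topmost_then_leftmost(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[3:7, 2:8] = CORNEA
        contour = extract_class_contour(mask, CORNEA)
        assert contour.points[0].tolist() == [2.0, 3.0]

    def test_largest_component_wins(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[2:4, 2:4] = CORNEA          # small island (noise)
        mask[10:25, 10:25] = CORNEA      # dominant region
        contour = extract_class_contour(mask, CORNEA)
        assert contour.points[:, 0].min() >= 10

    def test_missing_class_raises_named_error(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        with pytest.raises(EmptyClassError, match="3"):
            extract_class_contour(mask, 3)

    def test_occluded_cornea_contour_contains_leading_edge(
            self, standard_spec, standard_phantom):
        mask, _ = standard_phantom
        contour = extract_class_contour(mask, CORNEA)
        cx, cy = standard_spec.cornea_center
        # invasion comes from direction 180 deg: the leading edge is the
        # near-vertical chord at x = cx - d
        proj = cx - contour.points[:, 0]  # (p - c) . u for u = (-1, 0)
        d = standard_spec.invasion_distance_px
        edge = np.abs(proj - d) <= 2.0
        r = np.hypot(contour.points[:, 0] - cx, contour.points[:, 1] - cy)
        limbal = np.abs(r - standard_spec.cornea_radius_px) <= 2.0
        assert edge.sum() > 50          # chord points present (the outliers)
        assert limbal.sum() > 500       # intact limbal arc present
        assert (edge | limbal).mean() > 0.95


class TestWeightFunctions:
    @pytest.mark.parametrize("kind,delta,gamma,expected", [
        ("tukey", 0.0, 1.0, 1.0),
        ("tukey", 1.5, 1.0, 0.0),
        ("tukey", -2.0, 1.0, 0.0),
        ("tukey", 0.5, 1.0, 0.5625),     # (1 - 0.25)^2
        ("huber", 0.0, 1.0, 1.0),
        ("huber", 2.0, 1.0, 0.5),        # gamma / |delta|
        ("huber", -4.0, 2.0, 0.5),
        ("uniform", 123.0, 1.0, 1.0),
    ])
    def test_closed_form_values(self, kind, delta, gamma, expected):
        spec = WeightFunctionSpec(kind, gamma)
        assert weight_value(spec, delta, gamma) == pytest.approx(
            expected, abs=1e-15)

    @settings(deadline=None, max_examples=50)
    @given(delta=st.floats(-100, 100), gamma=st.floats(0.01, 10))
    def test_weights_bounded_and_even(self, delta, gamma):
        for kind in ("huber", "tukey"):
            spec = WeightFunctionSpec(kind, gamma)
            w = weight_value(spec, delta, gamma)
            assert 0.0 <= w <= 1.0
            assert w == pytest.approx(
                weight_value(spec, -delta, gamma), abs=1e-12)

    def test_monotone_nonincreasing_in_abs_residual(self):
        deltas = np.linspace(0.0, 5.0, 200)
        for kind in ("huber", "tukey"):
            spec = WeightFunctionSpec(kind, 1.0)
            w = weight_value(spec, deltas, 1.3)
            assert w[0] == 1.0
            assert (np.diff(w) <= 1e-12).all()

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            weight_value(WeightFunctionSpec("huber", 1.0), 1.0, 0.0)
        with pytest.raises(ValueError):
            WeightFunctionSpec("tukey", -1.0)
        with pytest.raises(ValueError):
            WeightFunctionSpec("cauchy", 1.0)


class TestAlgebraicFit:
    def test_exact_circle_recovered(self):
        pts = circle_points(100.0, 100.0, 50.0, n=100)
        fit = fit_circle_algebraic(pts)
        assert fit.center[0] == pytest.approx(100.0, abs=1e-6)
        assert fit.center[1] == pytest.approx(100.0, abs=1e-6)
        assert fit.radius == pytest.approx(50.0, abs=1e-6)
        assert np.abs(fit.residuals).max() < 1e-6

    def test_three_point_circumcircle(self):
        fit = fit_circle_algebraic(np.array([[0.0, 0.0], [2.0, 0.0],
                                             [1.0, 1.0]]))
        assert fit.center[0] == pytest.approx(1.0, abs=1e-9)
        assert fit.center[1] == pytest.approx(0.0, abs=1e-9)
        assert fit.radius == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_circle_algebraic(np.array([[0.0, 0.0], [1.0, 1.0]]))
        collinear = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        with pytest.raises(DegenerateGeometryError):
            fit_circle_algebraic(collinear)


class TestIRLSFit:
    def test_uniform_weights_reduce_to_algebraic(self):
        rng = np.random.default_rng(0)
        pts = circle_points(50.0, 60.0, 30.0, n=120, rng=rng, noise_sd=0.5)
        irls = fit_circle_irls(pts, WeightFunctionSpec("uniform", 1.0))
        alg = fit_circle_algebraic(pts)
        assert irls.center == alg.center
        assert irls.radius == alg.radius

    @pytest.mark.parametrize("kind,occlusion,tol", [
        ("tukey", 0.3, 1.0),    # redescending weight: full rejection
        ("tukey", 0.4, 1.0),
        ("huber", 0.1, 1.0),    # monotone weight: robust only when the
        ("huber", 0.3, 25.0),   # occluded arc is short
    ])
    def test_occluded_circle_recovered(self, kind, occlusion, tol):
        rng = np.random.default_rng(3)
        pts = occluded_circle_points(256.0, 256.0, 200.0, occlusion, n=720,
                                     rng=rng, noise_sd=0.3)
        fit = fit_circle_irls(pts, WeightFunctionSpec(kind, "auto"))
        assert abs(fit.center[0] - 256.0) < tol
        assert abs(fit.center[1] - 256.0) < tol
        assert abs(fit.radius - 200.0) < tol

    def test_robust_beats_ordinary_least_squares(self):
        rng = np.random.default_rng(4)
        pts = occluded_circle_points(256.0, 256.0, 200.0, 0.35, n=720,
                                     rng=rng, noise_sd=0.3)
        tukey = fit_circle_irls(pts, WeightFunctionSpec("tukey", "auto"))
        ols = fit_circle_algebraic(pts)
        assert abs(tukey.radius - 200.0) < abs(ols.radius - 200.0)

    def test_breakdown_ordering_over_contamination(self):
        """Median radius error: tukey <= huber <= uniform, contamination
        up to 40%, aggregated over seeded replicates."""
        errors = {"tukey": [], "huber": [], "uniform": []}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            frac = rng.uniform(0.1, 0.4)
            pts = occluded_circle_points(256.0, 256.0, 200.0, frac,
                                         n=720, rng=rng, noise_sd=0.3)
            for kind in errors:
                fit = fit_circle_irls(pts, WeightFunctionSpec(kind, "auto"))
                errors[kind].append(abs(fit.radius - 200.0))
        med = {k: np.median(v) for k, v in errors.items()}
        assert med["tukey"] <= med["huber"] <= med["uniform"]

    def test_rigid_motion_equivariance(self):
        rng = np.random.default_rng(5)
        pts = occluded_circle_points(0.0, 0.0, 100.0, 0.25, n=360,
                                     rng=rng, noise_sd=0.2)
        base = fit_circle_irls(pts, WeightFunctionSpec("tukey", "auto"))
        angle = 0.7
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        shift = np.array([13.0, -42.0])
        moved = pts @ rot.T + shift
        fit = fit_circle_irls(moved, WeightFunctionSpec("tukey", "auto"))
        expected_center = rot @ np.array(base.center) + shift
        assert np.allclose(fit.center, expected_center, atol=1e-6)
        assert fit.radius == pytest.approx(base.radius, abs=1e-6)

    def test_reports_iteration_count_and_convergence(self):
        pts = circle_points(10.0, 10.0, 5.0, n=50)
        fit = fit_circle_irls(pts, WeightFunctionSpec("tukey", "auto"),
                              max_iterations=10, tolerance=1e-9)
        assert fit.converged
        assert 1 <= fit.n_iterations <= 10

    def test_weight_collapse_raises(self):
        rng = np.random.default_rng(6)
        pts = circle_points(0.0, 0.0, 50.0, n=100, rng=rng, noise_sd=2.0)
        with pytest.raises(WeightCollapseError, match="gamma"):
            fit_circle_irls(pts, WeightFunctionSpec("tukey", 1e-9))
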