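import numpy as np
import pytest

from pterygrade import (
    PhantomSpec,
    generate_phantom,
    grading_summary,
    per_class_metrics,
    perturb_mask,
    sweep_case_grades,
)
from pterygrade.metrics import (
    confusion_matrix,
    diameter_grid,
    diameter_sweep,
    summary_from_confusion,
    sweep_table,
)


def grades_from_confusion(conf):
    """Expand a confusion matrix into (pred, expert) grade lists."""
    preds, experts = [], []
    for e in range(conf.shape[0]):
        for p in range(conf.shape[1]):
            preds.extend([p + 1] * conf[e, p])
            experts.extend([e + 1] * conf[e, p])
    return preds, experts


class TestPerClassMetrics:
    def test_perfect_agreement(self):
        m = np.random.default_rng(0).integers(0, 4, (32, 32)).astype(np.uint8)
        cm = per_class_metrics(m, m, 2)
        assert cm.iou == cm.dice == cm.precision == cm.recall == 1.0

    def test_disjoint_regions(self):
        pred = np.zeros((10, 10), dtype=np.uint8)
        truth = np.zeros((10, 10), dtype=np.uint8)
        pred[:5] = 1
        truth[5:] = 1
        cm = per_class_metrics(pred, truth, 1)
        assert cm.iou == cm.dice == cm.precision == cm.recall == 0.0

    def test_shifted_square_counts(self):
        pred = np.zeros((20, 20), dtype=np.uint8)
        truth = np.zeros((20, 20), dtype=np.uint8)
        truth[4:12, 4:12] = 1
        pred[4:12, 6:14] = 1   # shifted 2 px right
        cm = per_class_metrics(pred, truth, 1)
        assert (cm.tp, cm.fp, cm.fn) == (48, 16, 16)
        assert cm.iou == pytest.approx(0.6)
        assert cm.dice == pytest.approx(0.75)

    def test_empty_class_convention(self):
        empty = np.zeros((8, 8), dtype=np.uint8)
        cm = per_class_metrics(empty, empty, 3)
        assert cm.iou == cm.dice == 1.0 and cm.undefined
        truth = empty.copy()
        truth[0, 0] = 3
        cm = per_class_metrics(empty, truth, 3)
        assert cm.precision == 0.0 and cm.undefined

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            per_class_metrics(np.zeros((4, 4)), np.zeros((5, 5)), 0)

    def test_dice_iou_identity_on_perturbed_phantoms(self):
        mask, _ = generate_phantom(PhantomSpec(seed=3))
        pred = perturb_mask(mask, 0.03, 1, seed=9)
        for code in range(4):
            cm = per_class_metrics(pred, mask, code)
            assert cm.dice == pytest.approx(2 * cm.iou / (1 + cm.iou),
                                            abs=1e-12)


class TestGradingSummary:
    def test_perfect_agreement(self):
        s = grading_summary([1, 2, 3, 2], [1, 2, 3, 2])
        assert s.accuracy == s.weighted_f1 == s.kappa == 1.0

    def test_chance_level_agreement_gives_zero_kappa(self):
        conf = np.array([[25, 25, 0], [25, 25, 0], [0, 0, 0]])
        preds, experts = grades_from_confusion(conf)
        s = grading_summary(preds, experts)
        assert s.accuracy == pytest.approx(0.5)
        assert s.kappa == pytest.approx(0.0, abs=1e-12)

    def test_against_reference_implementation(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        conf = np.array([[40, 6, 0], [4, 58, 3], [0, 2, 12]])
        preds, experts = grades_from_confusion(conf)
        s = grading_summary(preds, experts)
        assert s.accuracy == pytest.approx(
            sklearn_metrics.accuracy_score(experts, preds), abs=1e-9)
        assert s.weighted_f1 == pytest.approx(
            sklearn_metrics.f1_score(experts, preds, average="weighted"),
            abs=1e-9)
        assert s.kappa == pytest.approx(
            sklearn_metrics.cohen_kappa_score(experts, preds), abs=1e-9)
        assert np.array_equal(
            s.confusion, sklearn_metrics.confusion_matrix(experts, preds))

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        preds = list(rng.integers(1, 4, 60))
        experts = list(rng.integers(1, 4, 60))
        s1 = grading_summary(preds, experts)
        perm = rng.permutation(60)
        s2 = grading_summary([preds[i] for i in perm],
                             [experts[i] for i in perm])
        assert s1.accuracy == s2.accuracy
        assert s1.weighted_f1 == s2.weighted_f1
        assert s1.kappa == s2.kappa

    def test_weighted_f1_reduces_to_plain_f1_single_class(self):
        # every expert label is grade 2 -> weight vector is (0, 1, 0)
        experts = [2] * 10
        preds = [2] * 7 + [1] * 3
        s = grading_summary(preds, experts)
        tp, fn, fp = 7, 3, 0
        assert s.weighted_f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            grading_summary([], [])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([1, 2], [1])


@pytest.fixture(scope="module")
def sweep_cases():
    cases = []
    for i, beta in enumerate((0.05, 0.20, 0.30, 0.40)):
        spec = PhantomSpec(
            invasion_distance_px=200.0 * (1 - 2 * beta),
            pupil_radius_px=40.0, seed=i,
            invasion_direction_deg=45.0 * i)
        mask, truth = generate_phantom(spec)
        cases.append((mask, truth.grade_true(11.5)))
    return cases


class TestDiameterSweep:

    def test_grid_has_eleven_default_rows(self):
        grid = diameter_grid()
        assert len(grid) == 11
        assert grid[0] == 11.5 and grid[-1] == 12.5

    def test_step_validation(self):
        with pytest.raises(ValueError):
            diameter_grid(step=0.0)
        with pytest.raises(ValueError):
            diameter_sweep([], 11.5, 12.5, 0.1)

    def test_all_grade_three_is_diameter_independent(self):
        masks = []
        for i in range(3):
            spec = PhantomSpec(invasion_distance_px=15.0,
                               pupil_radius_px=60.0, seed=i)
            masks.append(generate_phantom(spec)[0])
        summaries = diameter_sweep([(m, 3) for m in masks])
        assert len(summaries) == 11
        assert all(s.accuracy == 1.0 for s in summaries)

    def test_grade_three_assignments_identical_across_diameters(
            self, sweep_cases):
        _, grades, _ = sweep_case_grades(sweep_cases)
        is3 = grades == 3
        assert (is3.all(axis=1) | (~is3).any(axis=1)).all()
        for row in is3:
            assert row.all() or not row.any()

    def test_boundary_case_flips_at_predicted_diameter(self):
        """A case with measured beta flips grade 2 -> 1 exactly where
        beta * L crosses 3 mm."""
        from pterygrade import assess_image
        spec = PhantomSpec(invasion_distance_px=200.0 * (1 - 2 * 0.25),
                           pupil_radius_px=40.0)
        mask, _ = generate_phantom(spec)
        beta = assess_image(mask).metrics.beta
        flip_at = 3.0 / beta     # ~12.0 for beta ~0.25
        diameters, grades, _ = sweep_case_grades([(mask, 2)])
        expected = np.where(diameters * beta > 3.0, 2, 1)
        assert grades[0].tolist() == expected.tolist()
        assert 11.5 < flip_at < 12.5  # the flip is inside the sweep range

    def test_sweep_table_columns(self, sweep_cases):
        table = sweep_table(diameter_sweep(sweep_cases))
        assert list(table.columns) == ["reference_diameter_mm", "accuracy",
                                       "weighted_f1", "kappa"]
        assert len(table) == 11


class TestSummaryIdentities:
    def test_random_confusions_match_reference(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(12)
        for _ in range(100):
            conf = rng.integers(0, 30, (3, 3))
            if conf.sum() == 0:
                continue
            preds, experts = grades_from_confusion(conf)
            s = summary_from_confusion(conf, 11.5)
            assert s.accuracy == pytest.approx(
                sklearn_metrics.accuracy_score(experts, preds), abs=1e-9)
            labels = [1, 2, 3]
            assert s.weighted_f1 == pytest.approx(
                sklearn_metrics.f1_score(experts, preds, average="weighted",
                                         labels=labels, zero_division=0),
                abs=1e-9)
            if len(set(preds) | set(experts)) > 1:
                assert s.kappa == pytest.approx(
                    sklearn_metrics.cohen_kappa_score(experts, preds,
                                                      labels=labels),
                    abs=1e-9)
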