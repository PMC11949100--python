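"""Invasion quantification and clinical severity grading.

From a label mask and the robustly reconstructed corneal/pupillary
circles this module computes:

* the invasion area ratio ``alpha = A_p / A_c``, where ``A_p`` counts
  pterygium pixels inside the fitted disc and ``A_c`` counts all pixels of
  the fitted (restored) disc;
* the invasion depth ratio ``beta = (L/2 - d_min) / L``, where ``d_min``
  is the minimum distance from the fitted corneal centre to the visible
  corneal contour and ``L = 2r`` the fitted corneal diameter;
* the physical depth ``beta * L_ref`` for a reference adult corneal
  diameter ``L_ref`` (11.5-12.5 mm, default 11.5 mm);
* whether the lesion covers the pupil.

The clinical grade follows the three-level rule: grade 3 when the pupil
is covered, otherwise grade 2 when the invasion depth exceeds 3 mm and
grade 1 when it is at most 3 mm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from .fitting import (
    CircleFit,
    ContourPointSet,
    EmptyClassError,
    WeightFunctionSpec,
    extract_class_contour,
    fit_circle_irls,
)
from .palette import CORNEA, PTERYGIUM, PUPIL
from .phantom import LabelMask

GRADE_DEPTH_THRESHOLD_MM = 3.0
DEFAULT_REFERENCE_DIAMETER_MM = 11.5
DEFAULT_PUPIL_EPSILON = 0.005
# pupil radius assumed when the pupil class is missing but a lesion is
# present: fraction of the fitted corneal radius, concentric prior
FALLBACK_PUPIL_RADIUS_FRACTION = 0.3


class UnassessableMaskError(ValueError):
    """Raised when a mask cannot be graded (e.g. no cornea class)."""


class DiscOutOfFrameError(ValueError):
    """Raised when the fitted disc contains no in-frame pixel centres."""


@dataclass(frozen=True)
class AssessmentConfig:
    """Tunable parameters of the assessment pipeline."""

    weight: WeightFunctionSpec = field(default_factory=WeightFunctionSpec)
    max_iterations: int = 10
    tolerance: float = 1e-6
    reference_diameter_mm: float = DEFAULT_REFERENCE_DIAMETER_MM
    pupil_epsilon: float = DEFAULT_PUPIL_EPSILON


@dataclass(frozen=True)
class InvasionMetrics:
    """Quantified pterygium invasion for one image."""

    alpha_cornea: float
    alpha_pupil: float
    d_min_px: float
    L_px: float
    beta: float
    depth_mm: float
    reference_diameter_mm: float
    pupil_covered: bool
    disc_truncated: bool = False
    pupil_fit_fallback: bool = False


@dataclass(frozen=True)
class GradeResult:
    """Clinical grade with the rule that fired and full diagnostics."""

    grade: int
    rule_fired: str
    metrics: InvasionMetrics
    cornea_fit: CircleFit | None = None
    pupil_fit: CircleFit | None = None


def _disc_pixel_mask(shape: tuple[int, int], fit: CircleFit) -> np.ndarray:
    H, W = shape
    cx, cy = fit.center
    Y, X = np.ogrid[0:H, 0:W]
    return (X - cx) ** 2 + (Y - cy) ** 2 <= fit.radius**2


def _disc_truncated(shape: tuple[int, int], fit: CircleFit) -> bool:
    H, W = shape
    cx, cy = fit.center
    r = fit.radius
    return cx - r < 0 or cy - r < 0 or cx + r > W - 1 or cy + r > H - 1


def invasion_area_ratio(mask: LabelMask, fitted_circle: CircleFit) -> float:
    """Pterygium pixel fraction of the fitted (restored) disc.

    The denominator counts every in-frame pixel centre inside the fitted
    disc — the restored region, not just the visible class pixels.
    """
    inside = _disc_pixel_mask(mask.shape, fitted_circle)
    a_c = int(inside.sum())
    if a_c == 0:
        raise DiscOutOfFrameError("fitted disc lies entirely outside the image")
    a_p = int(((mask == PTERYGIUM) & inside).sum())
    return a_p / a_c


def invasion_depth(contour: ContourPointSet,
                   fitted_circle: CircleFit) -> tuple[float, float, float]:
    """Minimum centre-to-contour distance, fitted diameter, depth ratio.

    ``beta`` is clipped to [0, 0.5]: 0 when the contour reaches the fitted
    circle, 0.5 when the leading edge passes through the centre.
    """
    cx, cy = fitted_circle.center
    d_min = float(np.hypot(contour.points[:, 0] - cx,
                           contour.points[:, 1] - cy).min())
    L = 2.0 * fitted_circle.radius
    beta = float(np.clip((L / 2.0 - d_min) / L, 0.0, 0.5))
    return d_min, L, beta


def physical_depth(beta: float, reference_diameter_mm: float) -> float:
    """Convert the depth ratio to millimetres via the reference diameter."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if not 11.5 <= reference_diameter_mm <= 12.5:
        warnings.warn(
            f"reference diameter {reference_diameter_mm} mm is outside the "
            "common adult range 11.5-12.5 mm", stacklevel=2)
    return beta * reference_diameter_mm


def pupil_coverage(mask: LabelMask, pupil_circle: CircleFit,
                   epsilon_fraction: float = DEFAULT_PUPIL_EPSILON) -> bool:
    """True when lesion pixels inside the fitted pupil disc exceed
    ``epsilon_fraction`` of the disc's pixel count.

    The epsilon tolerance keeps single-pixel segmentation noise from
    triggering grade 3.
    """
    inside = _disc_pixel_mask(mask.shape, pupil_circle)
    disc = int(inside.sum())
    if disc == 0:
        raise DiscOutOfFrameError("fitted pupil disc lies outside the image")
    covered = int(((mask == PTERYGIUM) & inside).sum())
    return covered > epsilon_fraction * disc


def grade_from_metrics(metrics: InvasionMetrics) -> tuple[int, str]:
    """Apply the three-level clinical rule to computed metrics.

    Pupil coverage takes precedence regardless of measured depth.
    """
    if metrics.pupil_covered:
        return 3, "pupil covered by pterygium"
    if metrics.depth_mm > GRADE_DEPTH_THRESHOLD_MM:
        return 2, (f"invasion depth {metrics.depth_mm:.2f} mm > "
                   f"{GRADE_DEPTH_THRESHOLD_MM} mm, pupil not covered")
    return 1, (f"invasion depth {metrics.depth_mm:.2f} mm <= "
               f"{GRADE_DEPTH_THRESHOLD_MM} mm")


def assess_image(mask: LabelMask,
                 config: AssessmentConfig = AssessmentConfig()) -> GradeResult:
    """Full assessment of one label mask.

    Pipeline: extract the corneal contour, reconstruct the corneal circle
    by IRLS, likewise for the pupil (falling back to a cornea-concentric
    prior when the pupil class is absent), quantify invasion, grade.
    Deterministic for a fixed mask and config.
    """
    mask = np.asarray(mask)
    if not (mask == CORNEA).any():
        raise UnassessableMaskError("mask contains no cornea class; unassessable")

    cornea_contour = extract_class_contour(mask, CORNEA)
    cornea_fit = fit_circle_irls(cornea_contour, config.weight,
                                 config.max_iterations, config.tolerance)
    logger.info(
        "cornea fit: center=(%.2f, %.2f) radius=%.2f iterations=%d "
        "rejected=%.1f%%", cornea_fit.center[0], cornea_fit.center[1],
        cornea_fit.radius, cornea_fit.n_iterations,
        100.0 * float(np.mean(np.asarray(cornea_fit.weights) < 1e-6)))
    logger.debug("cornea per-point weights: %s", cornea_fit.weights)

    pupil_fallback = False
    try:
        pupil_contour = extract_class_contour(mask, PUPIL)
        pupil_fit = fit_circle_irls(pupil_contour, config.weight,
                                    config.max_iterations, config.tolerance)
    except EmptyClassError:
        pupil_fallback = True
        pupil_fit = CircleFit(
            center=cornea_fit.center,
            radius=FALLBACK_PUPIL_RADIUS_FRACTION * cornea_fit.radius)

    has_pter = bool((mask == PTERYGIUM).any())
    alpha_cornea = invasion_area_ratio(mask, cornea_fit)
    alpha_pupil = invasion_area_ratio(mask, pupil_fit)
    d_min, L, beta = invasion_depth(cornea_contour, cornea_fit)
    if not has_pter:
        # a full corneal contour still has pixel-level radial scatter;
        # without a lesion there is no invasion by definition
        beta = 0.0
        d_min = max(d_min, cornea_fit.radius)
    depth_mm = physical_depth(beta, config.reference_diameter_mm)
    covered = has_pter and pupil_coverage(mask, pupil_fit, config.pupil_epsilon)

    metrics = InvasionMetrics(
        alpha_cornea=alpha_cornea,
        alpha_pupil=alpha_pupil,
        d_min_px=d_min,
        L_px=L,
        beta=beta,
        depth_mm=depth_mm,
        reference_diameter_mm=config.reference_diameter_mm,
        pupil_covered=covered,
        disc_truncated=_disc_truncated(mask.shape, cornea_fit),
        pupil_fit_fallback=pupil_fallback,
    )
    grade, rule = grade_from_metrics(metrics)
    return GradeResult(grade=grade, rule_fired=rule, metrics=metrics,
                       cornea_fit=cornea_fit, pupil_fit=pupil_fit)
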