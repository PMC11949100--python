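"""Synthetic anterior-segment label masks with analytically known geometry.

A phantom models the front of the eye as seen by a slit lamp after
semantic segmentation: a circular cornea, a pupil disc inside it, and a
pterygium invading from one side.  The lesion's portion inside the cornea
is a circular cap — the intersection of the cornea disc with the half
plane ``{p : (p - c) . u >= d}``, where ``c`` is the cornea centre, ``u``
the unit invasion direction and ``d`` the distance from the centre to the
leading edge.  Outside the limbus the lesion continues as a scleral apron
so the overall shape is the wing-like wedge seen clinically.

Because the geometry is closed-form, every downstream quantity (invasion
area fraction, minimum leading-edge distance, invasion depth ratio, pupil
coverage, clinical grade) has an analytic truth value stored alongside the
mask, which makes the whole assessment pipeline testable without any
clinical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .palette import BACKGROUND, CORNEA, PTERYGIUM, PUPIL

LabelMask = np.ndarray  # 2D uint8 array of class codes


def circular_cap_fraction(radius: float, distance: float) -> float:
    """Fraction of a disc of ``radius`` cut off by a chord at signed
    ``distance`` from the centre (positive distance -> minor cap).

    ``distance >= radius`` gives 0, ``distance <= -radius`` gives 1.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if distance >= radius:
        return 0.0
    if distance <= -radius:
        return 1.0
    r, d = radius, distance
    area = r * r * math.acos(d / r) - d * math.sqrt(r * r - d * d)
    return area / (math.pi * r * r)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of one synthetic phantom.

    ``invasion_distance_px`` is the distance from the cornea centre to the
    pterygium leading edge; any value >= ``cornea_radius_px`` means the
    lesion has not entered the cornea.  ``apron_extent_px`` controls how
    far the lesion extends outward past the limbus on the scleral side.
    """

    height_px: int = 512
    width_px: int = 512
    cornea_center: tuple[float, float] = (256.0, 256.0)  # (x, y)
    cornea_radius_px: float = 200.0
    pupil_radius_px: float = 60.0
    pupil_offset_px: tuple[float, float] = (0.0, 0.0)
    invasion_direction_deg: float = 180.0
    invasion_distance_px: float = 150.0
    apron_extent_px: float = 30.0
    boundary_jitter_sd_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.cornea_radius_px <= 0 or self.pupil_radius_px <= 0:
            raise ValueError("radii must be positive")
        if self.pupil_radius_px >= self.cornea_radius_px:
            raise ValueError("pupil radius must be smaller than cornea radius")
        off = math.hypot(*self.pupil_offset_px)
        if off + self.pupil_radius_px > self.cornea_radius_px:
            raise ValueError("pupil disc must lie entirely inside the cornea disc")
        if self.invasion_distance_px < 0:
            raise ValueError("invasion_distance_px must be non-negative")
        if self.apron_extent_px < 0 or self.boundary_jitter_sd_px < 0:
            raise ValueError("apron extent and jitter sd must be non-negative")

    @property
    def pupil_center(self) -> tuple[float, float]:
        return (
            self.cornea_center[0] + self.pupil_offset_px[0],
            self.cornea_center[1] + self.pupil_offset_px[1],
        )


# fraction of the pupil disc the lesion must cover before the phantom truth
# calls the pupil "covered"; mirrors the grading module's default epsilon
PUPIL_COVERED_EPSILON = 0.005


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form ground truth for one phantom."""

    alpha_cornea_analytic: float
    d_min_true_px: float
    beta_true: float
    pupil_covered_frac: float
    pupil_covered_true: bool

    def grade_true(self, reference_diameter_mm: float = 11.5) -> int:
        """Clinical grade implied by the analytic geometry.

        Grade 3 if the lesion covers the pupil; otherwise grade 2 when the
        physical invasion depth exceeds 3 mm, grade 1 when it is <= 3 mm.
        """
        if self.pupil_covered_true:
            return 3
        depth_mm = self.beta_true * reference_diameter_mm
        return 2 if depth_mm > 3.0 else 1

    def depth_mm_true(self, reference_diameter_mm: float = 11.5) -> float:
        return self.beta_true * reference_diameter_mm


def _truth_for(spec: PhantomSpec) -> PhantomTruth:
    R = spec.cornea_radius_px
    d = min(max(spec.invasion_distance_px, 0.0), R)
    alpha = circular_cap_fraction(R, d)
    d_min = d
    beta = (R - d_min) / (2.0 * R) if spec.invasion_distance_px < R else 0.0

    if spec.invasion_distance_px >= R:
        covered_frac = 0.0
    else:
        theta = math.radians(spec.invasion_direction_deg)
        ux, uy = math.cos(theta), math.sin(theta)
        # signed distance from pupil centre to the cap edge, along u
        t = spec.invasion_distance_px - (
            spec.pupil_offset_px[0] * ux + spec.pupil_offset_px[1] * uy
        )
        covered_frac = circular_cap_fraction(spec.pupil_radius_px, t)
    return PhantomTruth(
        alpha_cornea_analytic=alpha,
        d_min_true_px=d_min,
        beta_true=beta,
        pupil_covered_frac=covered_frac,
        pupil_covered_true=covered_frac > PUPIL_COVERED_EPSILON,
    )


def _jitter_field(shape: tuple[int, int], sd: float, rng: np.random.Generator,
                  smooth_px: float = 6.0) -> np.ndarray:
    """Smooth zero-mean noise field with pointwise standard deviation sd."""
    if sd == 0.0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, smooth_px)
    s = smooth.std()
    if s == 0:
        return np.zeros(shape)
    return smooth * (sd / s)


def generate_phantom(spec: PhantomSpec) -> tuple[LabelMask, PhantomTruth]:
    """Render the phantom mask and its analytic truth.

    Classes are mutually exclusive with pterygium taking precedence over
    cornea and pupil: the cornea class is the cornea disc minus the lesion
    cap minus the visible pupil, so its outer boundary is the "incomplete"
    corneal contour the fitting stage expects.
    """
    H, W = spec.height_px, spec.width_px
    cx, cy = spec.cornea_center
    Y, X = np.mgrid[0:H, 0:W].astype(float)

    rng = np.random.default_rng(spec.seed)
    dist_c = np.hypot(X - cx, Y - cy)
    theta = math.radians(spec.invasion_direction_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    proj = (X - cx) * ux + (Y - cy) * uy

    sd = spec.boundary_jitter_sd_px
    limbus_jitter = _jitter_field((H, W), sd, rng)
    edge_jitter = _jitter_field((H, W), sd, rng)

    in_cornea = dist_c <= spec.cornea_radius_px + limbus_jitter
    in_cap = proj >= spec.invasion_distance_px + edge_jitter

    px, py = spec.pupil_center
    dist_p = np.hypot(X - px, Y - py)
    in_pupil = dist_p <= spec.pupil_radius_px + limbus_jitter

    apron = in_cap & ~in_cornea & (
        dist_c <= spec.cornea_radius_px + spec.apron_extent_px + limbus_jitter
    )
    # a leading edge at or beyond the limbus means the lesion has not
    # entered the cornea: only the scleral apron may be present
    invaded = spec.invasion_distance_px < spec.cornea_radius_px
    pter = ((in_cap & in_cornea) if invaded else np.zeros_like(in_cap)) | apron

    mask = np.full((H, W), BACKGROUND, dtype=np.uint8)
    mask[in_cornea] = CORNEA
    mask[in_pupil & in_cornea] = PUPIL
    mask[pter] = PTERYGIUM
    return mask, _truth_for(spec)


def sample_benchmark_phantoms(
        n: int, seed: int, size: int = 512,
        reference_diameter_mm: float = 11.5,
        depth_margin_mm: float = 0.2,
        pupil_margin_px: float = 3.0,
        covered_fraction: float = 0.25,
        boundary_jitter_sd_px: float = 0.0,
        max_clear_beta: float = 0.345,
) -> list[tuple[LabelMask, PhantomTruth, PhantomSpec]]:
    """Seeded family of phantoms for benchmarking the assessment pipeline.

    The family mixes pupil-covered cases (``covered_fraction`` of the
    draws) with clear-pupil cases whose physical invasion depth stays at
    least ``depth_margin_mm`` away from the 3 mm grading threshold and
    whose leading edge keeps ``pupil_margin_px`` of clearance from the
    pupil boundary — i.e. cases a clinician would grade unambiguously.
    Clear-pupil depth ratios are capped at ``max_clear_beta`` so the
    occluded arc stays within the ~40% contamination the robust fit is
    designed for; covered cases may exceed it (their grade is decided by
    pupil coverage, not by the depth estimate).

    Boundary jitter defaults to zero here: the family's analytic truth
    describes the noise-free geometry, and the depth-ratio oracle is only
    exact when the rendered leading edge coincides with it.  Robustness
    to boundary noise is exercised separately via ``perturb_mask`` and
    occluded-contour fitting benchmarks.
    """
    rng = np.random.default_rng(seed)
    boundary_beta = 3.0 / reference_diameter_mm
    band = depth_margin_mm / reference_diameter_mm
    out = []
    while len(out) < n:
        R = rng.uniform(0.29, 0.41) * size
        cx = size / 2 + rng.uniform(-8, 8)
        cy = size / 2 + rng.uniform(-8, 8)
        direction = rng.uniform(0.0, 360.0)
        ux, uy = math.cos(math.radians(direction)), math.sin(
            math.radians(direction))
        r_p = rng.uniform(0.20, 0.30) * R
        off = rng.uniform(-0.06, 0.06, 2) * R
        if math.hypot(*off) + r_p > 0.95 * R:
            continue
        off_u = off[0] * ux + off[1] * uy

        if rng.random() < covered_fraction:
            hi = r_p - pupil_margin_px + off_u
            if hi <= 1.0:
                continue
            d = rng.uniform(0.0, hi)
        else:
            beta = rng.uniform(0.02, max_clear_beta)
            if abs(beta - boundary_beta) < band:
                continue
            d = R * (1.0 - 2.0 * beta)
            if d - off_u < r_p + pupil_margin_px:
                continue
        spec = PhantomSpec(
            height_px=size, width_px=size, cornea_center=(cx, cy),
            cornea_radius_px=R, pupil_radius_px=r_p,
            pupil_offset_px=(float(off[0]), float(off[1])),
            invasion_direction_deg=direction,
            invasion_distance_px=float(d),
            apron_extent_px=0.15 * R,
            boundary_jitter_sd_px=boundary_jitter_sd_px,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mask, truth = generate_phantom(spec)
        out.append((mask, truth, spec))
    return out


def perturb_mask(mask: LabelMask, flip_fraction: float,
                 boundary_erode_dilate_px: int, seed: int) -> LabelMask:
    """Simulate segmentation error on a clean label mask.

    Two seed-deterministic perturbations are applied:

    * ``boundary_erode_dilate_px`` dilates (positive) or erodes (negative)
      the pterygium region; pixels the lesion vacates revert to cornea,
      emulating leading-edge over/under-segmentation.
    * ``flip_fraction`` of all pixels (capped by the band size) are
      relabelled within a 1-px band around class boundaries, each flipped
      pixel taking the class of a random 8-neighbour.  Confining label
      noise to boundaries mirrors how segmentation networks actually err;
      uniform salt-and-pepper noise would not.
    """
    if not 0.0 <= flip_fraction < 1.0:
        raise ValueError("flip_fraction must be in [0, 1)")
    out = mask.copy()
    rng = np.random.default_rng(seed)

    k = int(boundary_erode_dilate_px)
    if k != 0:
        pter = out == PTERYGIUM
        structure = ndimage.generate_binary_structure(2, 2)
        if k > 0:
            new_pter = ndimage.binary_dilation(pter, structure, iterations=k)
        else:
            new_pter = ndimage.binary_erosion(pter, structure, iterations=-k)
        freed = pter & ~new_pter
        out[freed] = CORNEA
        out[new_pter] = PTERYGIUM

    if flip_fraction > 0.0:
        structure = ndimage.generate_binary_structure(2, 2)
        boundary = np.zeros(out.shape, dtype=bool)
        for code in np.unique(out):
            region = out == code
            boundary |= region & ~ndimage.binary_erosion(region, structure)
        band_idx = np.flatnonzero(boundary)
        n_flip = min(int(round(flip_fraction * out.size)), band_idx.size)
        if n_flip > 0:
            chosen = rng.choice(band_idx, size=n_flip, replace=False)
            ys, xs = np.unravel_index(chosen, out.shape)
            H, W = out.shape
            dy = rng.integers(-1, 2, size=n_flip)
            dx = rng.integers(-1, 2, size=n_flip)
            ny = np.clip(ys + dy, 0, H - 1)
            nx = np.clip(xs + dx, 0, W - 1)
            out[ys, xs] = mask[ny, nx]
    return out
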