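import numpy as np
import pytest

from pterygrade.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def standard_spec() -> PhantomSpec:
    """512x512 phantom with a moderate lesion (d = 0.75 R)."""
    return PhantomSpec(
        height_px=512, width_px=512, cornea_center=(256.0, 256.0),
        cornea_radius_px=200.0, pupil_radius_px=60.0,
        invasion_direction_deg=180.0, invasion_distance_px=150.0,
        apron_extent_px=30.0, seed=0)


@pytest.fixture(scope="session")
def standard_phantom(standard_spec):
    return generate_phantom(standard_spec)


def circle_points(cx: float, cy: float, r: float, n: int = 200,
                  rng: np.random.Generator | None = None,
                  noise_sd: float = 0.0) -> np.ndarray:
    """Exact or noisy samples of a circle, as an (n, 2) array of (x, y)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    if noise_sd > 0:
        assert rng is not None
        pts += rng.normal(0.0, noise_sd, pts.shape)
    return pts


def occluded_circle_points(cx: float, cy: float, r: float,
                           occluded_fraction: float, n: int = 360,
                           rng: np.random.Generator | None = None,
                           noise_sd: float = 0.0) -> np.ndarray:
    """Circle samples with an arc replaced by its chord (the outliers).

    ``occluded_fraction`` of the arc, centred on angle 0, is replaced by
    uniformly spaced points on the chord connecting its endpoints —
    mimicking a lesion's leading edge across an otherwise circular
    contour.
    """
    phi = occluded_fraction * np.pi  # half-angle of the removed arc
    n_occ = int(round(occluded_fraction * n))
    theta = np.linspace(phi, 2.0 * np.pi - phi, n - n_occ)
    arc = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    # chord from angle -phi to +phi at x = cx + r cos(phi)
    ys = np.linspace(cy - r * np.sin(phi), cy + r * np.sin(phi), max(n_occ, 2))
    chord = np.column_stack([np.full_like(ys, cx + r * np.cos(phi)), ys])
    pts = np.vstack([arc, chord])
    if noise_sd > 0:
        assert rng is not None
        pts += rng.normal(0.0, noise_sd, pts.shape)
    return pts
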