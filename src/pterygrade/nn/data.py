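"""Rendering phantoms as RGB images for smoke-scale network training.

Each class region is flat-shaded with an eye-plausible colour, a gentle
illumination gradient is overlaid and pixelwise Gaussian noise is added.
This is deliberately far easier than a slit-lamp photograph — it verifies
that the network, loss and optimiser wiring can learn a segmentation, not
that the architecture solves the clinical problem.
"""

from __future__ import annotations

import numpy as np

from ..palette import BACKGROUND, CORNEA, PTERYGIUM, PUPIL
from ..phantom import PhantomSpec, generate_phantom

# flat-shade base colours per class (RGB in [0, 1])
_SHADES = {
    BACKGROUND: (0.85, 0.80, 0.75),  # whitish sclera / skin
    PTERYGIUM: (0.80, 0.45, 0.45),   # pink fibrovascular tissue
    PUPIL: (0.08, 0.08, 0.10),       # dark pupil
    CORNEA: (0.45, 0.35, 0.30),      # iris seen through the cornea
}


def render_rgb(mask: np.ndarray, seed: int = 0,
               noise_sd: float = 0.06) -> np.ndarray:
    """Flat-shaded RGB rendering (3, H, W) of a label mask, float in [0,1]."""
    rng = np.random.default_rng(seed)
    H, W = mask.shape
    img = np.zeros((3, H, W))
    for code, shade in _SHADES.items():
        sel = mask == code
        for c in range(3):
            img[c][sel] = shade[c]
    # smooth illumination gradient across the frame
    gy = np.linspace(-0.05, 0.05, H)[:, None]
    gx = np.linspace(-0.05, 0.05, W)[None, :]
    img += (gy + gx)[None]
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def make_smoke_dataset(n: int, size: int = 128, seed: int = 0,
                       ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (image, mask) pairs of randomly parameterised phantoms."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        R = size * rng.uniform(0.30, 0.42)
        pr = R * rng.uniform(0.20, 0.35)
        cx = size / 2 + rng.uniform(-0.05, 0.05) * size
        cy = size / 2 + rng.uniform(-0.05, 0.05) * size
        spec = PhantomSpec(
            height_px=size, width_px=size,
            cornea_center=(cx, cy), cornea_radius_px=R, pupil_radius_px=pr,
            invasion_direction_deg=rng.uniform(0, 360),
            invasion_distance_px=R * rng.uniform(0.3, 1.1),
            apron_extent_px=R * 0.15,
            boundary_jitter_sd_px=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mask, _ = generate_phantom(spec)
        image = render_rgb(mask, seed=int(rng.integers(0, 2**31 - 1)))
        out.append((image, mask))
    return out
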