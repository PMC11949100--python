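"""Mask and report I/O plus run configuration.

Label masks travel as paletted PNG files (codes 0=background,
1=pterygium, 2=pupil, 3=cornea).  Grayscale PNGs holding raw codes and
RGB images in the default display palette are also accepted on read.
Assessment reports are schema-stable JSON with a full config echo.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import __version__
from .fitting import WeightFunctionSpec
from .grading import (
    AssessmentConfig,
    DEFAULT_PUPIL_EPSILON,
    DEFAULT_REFERENCE_DIAMETER_MM,
    GradeResult,
)
from .palette import DEFAULT_PALETTE, ClassPalette
from .phantom import LabelMask


class MaskFormatError(ValueError):
    """Raised for unreadable masks or unknown class codes."""


@dataclass(frozen=True)
class RunConfig:
    """Flat, schema-validated pipeline configuration.

    Defaults follow the assessment protocol: Tukey weights with the
    scale-adaptive gamma, 10 IRLS iterations, 11.5 mm reference diameter.
    """

    weight: str = "tukey"
    gamma: float | str = "auto"
    max_iterations: int = 10
    tolerance: float = 1e-6
    reference_diameter_mm: float = DEFAULT_REFERENCE_DIAMETER_MM
    pupil_epsilon: float = DEFAULT_PUPIL_EPSILON
    seed: int = 0

    def to_assessment_config(self) -> AssessmentConfig:
        return AssessmentConfig(
            weight=WeightFunctionSpec(kind=self.weight, gamma_policy=self.gamma),
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
            reference_diameter_mm=self.reference_diameter_mm,
            pupil_epsilon=self.pupil_epsilon,
        )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key/value YAML document, applying overrides."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def write_mask(mask: LabelMask, path: str | Path,
               palette: ClassPalette = DEFAULT_PALETTE) -> None:
    """Write a label mask as a paletted PNG."""
    arr = np.asarray(mask, dtype=np.uint8)
    img = Image.fromarray(arr, mode="P")
    img.putpalette(palette.flat_palette())
    img.save(path)


def read_mask(path: str | Path,
              palette: ClassPalette = DEFAULT_PALETTE) -> LabelMask:
    """Read a paletted/grayscale/RGB-encoded mask and validate its codes."""
    try:
        img = Image.open(path)
    except Exception as exc:  # unreadable file
        raise MaskFormatError(f"cannot read mask {path}: {exc}") from exc
    if img.mode in ("P", "L"):
        arr = np.asarray(img, dtype=np.int64)
    elif img.mode in ("RGB", "RGBA"):
        rgb = np.asarray(img.convert("RGB"), dtype=np.int64)
        arr = np.full(rgb.shape[:2], -1, dtype=np.int64)
        for code, color in palette.colors.items():
            arr[(rgb == np.array(color)).all(axis=-1)] = code
        if (arr < 0).any():
            bad = np.unique(rgb[arr < 0].reshape(-1, 3), axis=0)
            raise MaskFormatError(
                f"mask {path} contains colors outside the palette: "
                f"{bad[:5].tolist()}")
    else:
        raise MaskFormatError(f"unsupported mask image mode {img.mode!r}")

    codes = set(palette.codes)
    present = np.unique(arr)
    unknown = [int(c) for c in present if int(c) not in codes]
    if unknown:
        counts = {int(c): int((arr == c).sum()) for c in unknown}
        raise MaskFormatError(
            f"mask {path} contains unknown class codes (code: count): {counts}")
    return arr.astype(np.uint8)


def result_to_dict(result: GradeResult, config: RunConfig | None = None) -> dict:
    m = result.metrics
    out = {
        "tool_version": __version__,
        "grade": result.grade,
        "rule_fired": result.rule_fired,
        "alpha_cornea": m.alpha_cornea,
        "alpha_pupil": m.alpha_pupil,
        "d_min_px": m.d_min_px,
        "L_px": m.L_px,
        "beta": m.beta,
        "depth_mm": m.depth_mm,
        "reference_diameter_mm": m.reference_diameter_mm,
        "pupil_covered": m.pupil_covered,
        "disc_truncated": m.disc_truncated,
        "pupil_fit_fallback": m.pupil_fit_fallback,
        "fits": {},
        "config": dataclasses.asdict(config) if config else None,
    }
    for name, fit in (("cornea", result.cornea_fit), ("pupil", result.pupil_fit)):
        if fit is None:
            continue
        out["fits"][name] = {
            "center": [float(fit.center[0]), float(fit.center[1])],
            "radius": float(fit.radius),
            "n_iterations": fit.n_iterations,
            "converged": fit.converged,
            "n_points": int(len(fit.weights)),
            "rejected_fraction": float(np.mean(np.asarray(fit.weights) < 1e-6))
            if len(fit.weights) else 0.0,
        }
    return out


def write_report(result: GradeResult, path: str | Path,
                 config: RunConfig | None = None) -> None:
    """Write the assessment report as stable, round-trippable JSON."""
    Path(path).write_text(
        json.dumps(result_to_dict(result, config), indent=2, sort_keys=True)
        + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
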