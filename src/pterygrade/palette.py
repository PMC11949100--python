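"""Class codes and display palette for anterior-segment label masks.

The pipeline's central currency is a 2D integer label mask over four
mutually exclusive classes: background, pterygium, pupil and cornea.
Masks are interchanged as paletted PNG files using the display colours
defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BACKGROUND = 0
PTERYGIUM = 1
PUPIL = 2
CORNEA = 3

DEFAULT_NAMES = {
    BACKGROUND: "background",
    PTERYGIUM: "pterygium",
    PUPIL: "pupil",
    CORNEA: "cornea",
}

DEFAULT_COLORS = {
    BACKGROUND: (0, 0, 0),
    PTERYGIUM: (220, 60, 60),
    PUPIL: (60, 60, 220),
    CORNEA: (90, 200, 120),
}


@dataclass(frozen=True)
class ClassPalette:
    """Bijective mapping class code <-> name <-> display RGB.

    Codes must be contiguous from 0; the default encodes the three
    annotated anterior-segment regions plus background.
    """

    names: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_NAMES))
    colors: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS)
    )

    def __post_init__(self) -> None:
        codes = sorted(self.names)
        if codes != list(range(len(codes))):
            raise ValueError(f"class codes must be contiguous from 0, got {codes}")
        if set(self.colors) != set(self.names):
            raise ValueError("names and colors must cover the same codes")
        if len(set(self.names.values())) != len(self.names):
            raise ValueError("class names must be unique")
        if len(set(self.colors.values())) != len(self.colors):
            raise ValueError("display colors must be unique")

    @property
    def codes(self) -> list[int]:
        return sorted(self.names)

    def code_for(self, name: str) -> int:
        for code, n in self.names.items():
            if n == name:
                return code
        raise KeyError(f"unknown class name {name!r}")

    def flat_palette(self) -> list[int]:
        """PNG palette as a flat [r0,g0,b0, r1,g1,b1, ...] list."""
        out: list[int] = []
        for code in self.codes:
            out.extend(self.colors[code])
        return out


DEFAULT_PALETTE = ClassPalette()
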