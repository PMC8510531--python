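"""Color representation and pixel color distance calculation (PCDC).

Pixel colors are compared in a *normalized* CIELAB frame.  Standard CIELAB
coordinates (``L*`` in 0–100, ``a*``/``b*`` roughly −128..127) are rescaled
as::

    lam = L* / 100        alp = a* / 255        bet = b* / 255

so that the whole space fits inside a sphere of diameter 1 whose center
``(0.5, 0, 0)`` is mid-gray (``L* = 50, a* = b* = 0``).  The distance of a
pixel to a target color *c* is plain Euclidean distance in this frame; it is
normalized by the largest distance attainable from *c*,

    d_max(c) = |c − center| + 0.5,

giving a score ``d_s = d / d_max`` in [0, 1]: 0 means the pixel *is* the
target color, 1 means it is maximally different from it.

sRGB input is assumed (D65 white point, 2° observer, standard sRGB transfer
function) — the dominant convention for consumer camera imagery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "SRGBColor",
    "LabColor",
    "ColorDistance",
    "SPHERE_CENTER",
    "SPHERE_RADIUS",
    "L_SCALE",
    "AB_SCALE",
    "parse_hex",
    "srgb_to_lab",
    "lab_from_cielab",
    "image_to_lab",
    "color_distance",
    "max_distance",
    "normalized_distance",
    "normalized_distance_map",
    "pixel_distance",
]

#: Scale dividing L* to obtain the normalized lightness coordinate.
L_SCALE = 100.0
#: Scale dividing a* and b* to obtain the normalized opponent coordinates.
AB_SCALE = 255.0
#: Mid-gray (L*=50, a*=0, b*=0) in the normalized frame.
SPHERE_CENTER = (0.5, 0.0, 0.0)
#: Radius of the unit-diameter sphere enclosing the normalized space.
SPHERE_RADIUS = 0.5

_HEX_RE = re.compile(r"\A#?([0-9a-fA-F]{6})\Z")


def parse_hex(text: str) -> tuple[int, int, int]:
    """Parse a 6-digit hex color (case-insensitive, optional leading ``#``)."""
    m = _HEX_RE.match(text.strip())
    if m is None:
        raise ValueError(f"not a 6-hex-digit color: {text!r}")
    h = m.group(1)
    return tuple(int(h[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


@dataclass(frozen=True)
class SRGBColor:
    """An 8-bit sRGB color."""

    r: int
    g: int
    b: int

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 255):
                raise ValueError(f"channel {name}={v!r} outside 0–255")

    @classmethod
    def from_hex(cls, text: str) -> "SRGBColor":
        return cls(*parse_hex(text))

    def to_hex(self) -> str:
        return f"{self.r:02X}{self.g:02X}{self.b:02X}"

    def as_float(self) -> np.ndarray:
        """Channels scaled to [0, 1] floats."""
        return np.array([self.r, self.g, self.b], dtype=float) / 255.0


@dataclass(frozen=True)
class LabColor:
    """A color in the normalized CIELAB frame (see module docstring)."""

    lam: float  # normalized lightness, L*/100
    alp: float  # normalized green–red axis, a*/255
    bet: float  # normalized blue–yellow axis, b*/255

    def as_array(self) -> np.ndarray:
        return np.array([self.lam, self.alp, self.bet], dtype=float)


@dataclass(frozen=True)
class ColorDistance:
    """Raw and normalized distance of one color to a target color."""

    d: float
    d_max: float
    d_s: float


def _as_srgb(c: "SRGBColor | str") -> SRGBColor:
    return SRGBColor.from_hex(c) if isinstance(c, str) else c


def lab_from_cielab(L: float, a: float, b: float) -> LabColor:
    """Normalize standard CIELAB coordinates into the unit-sphere frame."""
    return LabColor(L / L_SCALE, a / AB_SCALE, b / AB_SCALE)


def srgb_to_lab(c: "SRGBColor | str") -> LabColor:
    """Convert an sRGB color (triple or hex string) to normalized CIELAB."""
    rgb = _as_srgb(c).as_float().reshape(1, 1, 3)
    L, a, b = _skcolor.rgb2lab(rgb).reshape(3)
    return lab_from_cielab(L, a, b)


def image_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert an H×W×3 uint8 sRGB image to normalized CIELAB coordinates.

    Returns a float H×W×3 array with channels (lam, alp, bet).
    """
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError(f"expected an H×W×3 image, got shape {rgb.shape}")
    lab = _skcolor.rgb2lab(np.asarray(rgb[..., :3], dtype=np.uint8))
    lab[..., 0] /= L_SCALE
    lab[..., 1] /= AB_SCALE
    lab[..., 2] /= AB_SCALE
    return lab


def color_distance(x: LabColor, y: LabColor) -> float:
    """Euclidean distance between two normalized-CIELAB colors."""
    return float(np.linalg.norm(x.as_array() - y.as_array()))


def max_distance(c: LabColor) -> float:
    """Largest distance attainable from *c* inside the unit-diameter sphere.

    Distance from *c* to the sphere center plus the sphere radius (0.5); 1.0
    when *c* lies on the sphere surface, 0.5 when *c* is the center itself.
    """
    center = LabColor(*SPHERE_CENTER)
    return color_distance(c, center) + SPHERE_RADIUS


def normalized_distance(pixel: LabColor, target: LabColor) -> float:
    """Normalized distance ``d_s = d / d_max`` of *pixel* to *target*, in [0, 1].

    Slightly out-of-sphere saturated colors are clamped so the score stays
    within the unit interval.
    """
    return float(np.clip(color_distance(pixel, target) / max_distance(target), 0.0, 1.0))


def pixel_distance(pixel: LabColor, target: LabColor) -> ColorDistance:
    """Full distance record (raw d, d_max, normalized d_s) for one pixel."""
    d = color_distance(pixel, target)
    dmax = max_distance(target)
    return ColorDistance(d=d, d_max=dmax, d_s=float(np.clip(d / dmax, 0.0, 1.0)))


def normalized_distance_map(lab_image: np.ndarray, target: LabColor) -> np.ndarray:
    """Per-pixel normalized distance of an H×W×3 normalized-Lab image to *target*."""
    diff = lab_image - target.as_array()
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    return np.clip(d / max_distance(target), 0.0, 1.0)
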