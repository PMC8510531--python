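"""Patch masking: background classification, denoising and hole filling.

A plate photograph of a single colony patch is turned into a binary mask in
three steps:

1. every pixel whose normalized color distance to the agar background color
   is at or below a cutoff is classified as background;
2. foreground connected components smaller than a fraction of the image
   (bubbles, agar imperfections) are removed;
3. interior background components smaller than a fraction of the image
   (unpigmented or glossy spots inside the colony) are filled.

Foreground components use 8-connectivity and background holes the dual
4-connectivity by default, avoiding the usual topological paradoxes; both
are configurable.  Size thresholds are strict: a component of exactly the
threshold size is left alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .colorspace import SRGBColor, image_to_lab, normalized_distance_map, srgb_to_lab
from .errors import MaskError, NoPatchError

__all__ = [
    "MaskingConfig",
    "BinaryMask",
    "CorrectionRecord",
    "classify_background",
    "remove_foreground_noise",
    "fill_holes",
    "make_patch_mask",
    "remove_small_components",
    "fill_small_holes",
    "count_components",
    "sample_background_color",
    "DEFAULT_BACKGROUND_COLOR",
    "DEFAULT_BACKGROUND_CUTOFF",
    "DEFAULT_NOISE_FRACTION",
    "DEFAULT_HOLE_FRACTION",
]

DEFAULT_BACKGROUND_COLOR = "33393E"
DEFAULT_BACKGROUND_CUTOFF = 0.15
DEFAULT_NOISE_FRACTION = 0.02
DEFAULT_HOLE_FRACTION = 0.20


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


@dataclass(frozen=True)
class MaskingConfig:
    """Parameters of the masking stage.

    background_cutoff is a normalized color distance in [0, 1];
    noise_fraction / hole_fraction are fractions of the total pixel count of
    the image below which a foreground component is deleted or a background
    hole is filled.
    """

    background_color: SRGBColor | str = DEFAULT_BACKGROUND_COLOR
    background_cutoff: float = DEFAULT_BACKGROUND_CUTOFF
    noise_fraction: float = DEFAULT_NOISE_FRACTION
    hole_fraction: float = DEFAULT_HOLE_FRACTION
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.background_cutoff < 1:
            raise ValueError("background_cutoff must lie strictly between 0 and 1")
        if not 0 < self.noise_fraction < self.hole_fraction < 1:
            raise ValueError("need 0 < noise_fraction < hole_fraction < 1")
        _structure(self.connectivity)

    @property
    def hole_connectivity(self) -> int:
        """Dual connectivity used for background components."""
        return 4 if self.connectivity == 8 else 8


@dataclass(frozen=True)
class CorrectionRecord:
    operation: str
    components_changed: int
    pixels_changed: int


@dataclass
class BinaryMask:
    """Per-pixel foreground raster with a log of corrections applied."""

    values: np.ndarray  # H×W bool, True = foreground (patch)
    corrections_log: list[CorrectionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be two-dimensional")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())


def sample_background_color(img: np.ndarray, region: tuple[int, int, int, int]) -> SRGBColor:
    """Average the pixels of a (y0, y1, x0, x1) rectangle into an agar color.

    Offered for plates whose agar differs from the packaged default; the
    fixed default color is otherwise used for every image.
    """
    y0, y1, x0, x1 = region
    patch = np.asarray(img[y0:y1, x0:x1, :3], dtype=float)
    if patch.size == 0:
        raise ValueError(f"empty sampling region {region}")
    r, g, b = np.round(patch.reshape(-1, 3).mean(axis=0)).astype(int)
    return SRGBColor(int(r), int(g), int(b))


def classify_background(img: np.ndarray, cfg: MaskingConfig | None = None) -> BinaryMask:
    """Threshold the per-pixel distance to the agar color into a binary mask.

    A pixel is background iff its normalized distance to
    ``cfg.background_color`` is ≤ ``cfg.background_cutoff``.
    """
    cfg = cfg or MaskingConfig()
    lab = image_to_lab(img)
    ds = normalized_distance_map(lab, srgb_to_lab(cfg.background_color))
    return BinaryMask(values=ds > cfg.background_cutoff)


def count_components(values: np.ndarray, connectivity: int = 8) -> int:
    _, n = ndimage.label(values, structure=_structure(connectivity))
    return int(n)


def remove_small_components(
    values: np.ndarray, min_size: float, connectivity: int = 8
) -> tuple[np.ndarray, int, int]:
    """Delete foreground components with strictly fewer than *min_size* pixels.

    Returns (new values, number of components removed, pixels removed).
    """
    labels, n = ndimage.label(values, structure=_structure(connectivity))
    if n == 0:
        return values.copy(), 0, 0
    sizes = np.bincount(labels.ravel())[1:]
    small = np.flatnonzero(sizes < min_size) + 1
    if small.size == 0:
        return values.copy(), 0, 0
    out = values.copy()
    kill = np.isin(labels, small)
    out[kill] = False
    return out, int(small.size), int(kill.sum())


def fill_small_holes(
    values: np.ndarray, max_size: float, hole_connectivity: int = 4
) -> tuple[np.ndarray, int, int]:
    """Fill interior background components with strictly fewer than *max_size* pixels.

    A hole is a background connected component that does not touch the image
    border; border-connected agar is never filled.
    """
    labels, n = ndimage.label(~values, structure=_structure(hole_connectivity))
    if n == 0:
        return values.copy(), 0, 0
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    sizes = np.bincount(labels.ravel())
    fillable = [
        lab
        for lab in range(1, n + 1)
        if lab not in border and sizes[lab] < max_size
    ]
    if not fillable:
        return values.copy(), 0, 0
    out = values.copy()
    fill = np.isin(labels, fillable)
    out[fill] = True
    return out, len(fillable), int(fill.sum())


def remove_foreground_noise(mask: BinaryMask, cfg: MaskingConfig | None = None) -> BinaryMask:
    """Remove small foreground specks (bubbles, agar imperfections).

    Raises NoPatchError if nothing is left after removal.
    """
    cfg = cfg or MaskingConfig()
    thresh = cfg.noise_fraction * mask.values.size
    out, ncomp, npix = remove_small_components(mask.values, thresh, cfg.connectivity)
    if not out.any():
        raise NoPatchError("no patch found: all foreground removed as noise")
    log = list(mask.corrections_log)
    log.append(CorrectionRecord("remove_foreground_noise", ncomp, npix))
    return BinaryMask(values=out, corrections_log=log)


def fill_holes(mask: BinaryMask, cfg: MaskingConfig | None = None) -> BinaryMask:
    """Fill small interior holes so they count as part of the patch."""
    cfg = cfg or MaskingConfig()
    thresh = cfg.hole_fraction * mask.values.size
    out, ncomp, npix = fill_small_holes(mask.values, thresh, cfg.hole_connectivity)
    log = list(mask.corrections_log)
    log.append(CorrectionRecord("fill_holes", ncomp, npix))
    return BinaryMask(values=out, corrections_log=log)


def make_patch_mask(img: np.ndarray, cfg: MaskingConfig | None = None) -> BinaryMask:
    """Full masking stage: classify, denoise, fill.

    The finalized mask must contain exactly one foreground component (the
    patch); otherwise MaskError / NoPatchError is raised.
    """
    cfg = cfg or MaskingConfig()
    mask = classify_background(img, cfg)
    if not mask.values.any():
        raise NoPatchError("no patch found: image classified entirely as background")
    mask = remove_foreground_noise(mask, cfg)
    mask = fill_holes(mask, cfg)
    n = count_components(mask.values, cfg.connectivity)
    if n != 1:
        raise MaskError(f"expected exactly one patch after corrections, found {n} components")
    return mask


def render_mask_image(mask: BinaryMask, foreground: SRGBColor | str, background: SRGBColor | str) -> np.ndarray:
    """Paint a mask as a flat two-color uint8 image (mainly for round-trip tests)."""
    fg = SRGBColor.from_hex(foreground) if isinstance(foreground, str) else foreground
    bg = SRGBColor.from_hex(background) if isinstance(background, str) else background
    out = np.empty((mask.height, mask.width, 3), dtype=np.uint8)
    out[...] = (bg.r, bg.g, bg.b)
    out[mask.values] = (fg.r, fg.g, fg.b)
    return out
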