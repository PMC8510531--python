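"""Spatial pigmentation profiles with baseline normalization.

Pigmentation of a foreground pixel is defined from its normalized color
distance ``d_s`` to the red pigment target color::

    p = 1 − d_s

A rectangular region of interest (ROI) spanning the patch horizontally and
20% of the maximum patch height vertically is split into 200 contiguous
column groups ("breakpoints").  Unpigmented wild-type patches are not at
p = 0 — lightness and shading contribute — so raw pigmentation is rescaled
against a baseline distribution Pb measured on isolated, unpigmented
patches:

    P_e = 0                          if P < Pb_min
    P_e = (P − Pb_min) / (1 − Pb_min)  otherwise

and a spatially specific correction removes systematic edge shading, per
pixel, using the baseline value of the pixel's breakpoint i expressed on
the same rescaled scale as P_e:

    P_f = P_e − (Pb_i − Pb_min) / (1 − Pb_min)      (floored at 0)

(the rescaling of the correction term keeps both operands in effective
units, so that an unpigmented patch corrects to zero everywhere).

The final profile is the per-breakpoint mean and standard deviation of P_f
over the foreground pixels of the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import SRGBColor, image_to_lab, normalized_distance_map, srgb_to_lab
from .errors import ProfileError
from .masking import BinaryMask, MaskingConfig, make_patch_mask

__all__ = [
    "N_BREAKPOINTS",
    "ROI_HEIGHT_FRACTION",
    "DEFAULT_PB_MIN",
    "DEFAULT_PIGMENT_COLOR",
    "ROI",
    "PigmentationProfile",
    "BaselineDistribution",
    "default_baseline",
    "pixel_pigmentation",
    "select_roi",
    "breakpoint_edges",
    "bin_breakpoints",
    "raw_profile",
    "compute_baseline",
    "baseline_from_images",
    "effective_pigmentation",
    "corrected_profile",
    "extract_profile",
]

#: Number of positional bins across the ROI's horizontal axis.
N_BREAKPOINTS = 200
#: ROI height as a fraction of the maximum patch height.
ROI_HEIGHT_FRACTION = 0.20
#: Baseline minimum shipped as the packaged default (flat baseline).
DEFAULT_PB_MIN = 0.342
#: Red pigment target color (average of strongly pigmented patch pixels).
DEFAULT_PIGMENT_COLOR = "803D33"


@dataclass(frozen=True)
class ROI:
    """Column/row bounds, 0-based half-open, of the profiling rectangle."""

    x0: int
    x1: int
    y0: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass
class PigmentationProfile:
    """200-breakpoint pigmentation profile of one patch.

    ``mean``/``sd`` are per-breakpoint statistics of corrected pigmentation
    P_f over foreground ROI pixels; ``n_pixels`` counts the pixels behind
    each bin (0 marks a bin whose mean was interpolated from neighbors).
    Bin 1 is the patch edge facing the interacting strain.
    """

    mean: np.ndarray
    sd: np.ndarray
    n_pixels: np.ndarray
    orientation: str = "interaction-first"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if not (len(self.mean) == len(self.sd) == len(self.n_pixels) == N_BREAKPOINTS):
            raise ValueError(f"profiles must have exactly {N_BREAKPOINTS} breakpoints")

    @property
    def n_bins(self) -> int:
        return len(self.mean)


@dataclass
class BaselineDistribution:
    """Per-breakpoint baseline pigmentation Pb of unpigmented patches."""

    pb: np.ndarray
    n_images: int = 0

    def __post_init__(self) -> None:
        self.pb = np.asarray(self.pb, dtype=float)
        if len(self.pb) != N_BREAKPOINTS:
            raise ValueError(f"baseline must have exactly {N_BREAKPOINTS} values")

    @property
    def pb_min(self) -> float:
        return float(self.pb.min())


def default_baseline(pb_min: float = DEFAULT_PB_MIN) -> BaselineDistribution:
    """Flat packaged baseline: every Pb_i equals pb_min.

    The spatial correction term is then zero while the P_e threshold keeps
    its standard value; recomputing the baseline from the user's own
    unpigmented wild-type plates is preferable whenever those exist.
    """
    return BaselineDistribution(pb=np.full(N_BREAKPOINTS, float(pb_min)), n_images=0)


def pixel_pigmentation(
    img: np.ndarray,
    mask: BinaryMask,
    pigment_color: SRGBColor | str = DEFAULT_PIGMENT_COLOR,
) -> np.ndarray:
    """Per-pixel pigmentation ``p = 1 − d_s`` w.r.t. the pigment target color.

    Background pixels are NaN and ignored downstream.
    """
    if img.shape[:2] != mask.values.shape:
        raise ValueError(
            f"image shape {img.shape[:2]} does not match mask shape {mask.values.shape}"
        )
    lab = image_to_lab(img)
    p = 1.0 - normalized_distance_map(lab, srgb_to_lab(pigment_color))
    p = p.astype(float)
    p[~mask.values] = np.nan
    return p


def select_roi(mask: BinaryMask, height_fraction: float = ROI_HEIGHT_FRACTION) -> ROI:
    """Vertically centered rectangle spanning the patch's horizontal extent.

    Height is ``round(height_fraction × maximum patch height)``, centered on
    the vertical midpoint of the patch bounding box.
    """
    rows = np.flatnonzero(mask.values.any(axis=1))
    cols = np.flatnonzero(mask.values.any(axis=0))
    if rows.size == 0:
        raise ProfileError("empty mask: no patch to profile")
    patch_height = int(rows[-1] - rows[0] + 1)
    if patch_height < 5:
        raise ProfileError(f"degenerate patch: height {patch_height} px is below 5 px")
    h = max(1, int(round(height_fraction * patch_height)))
    yc = (rows[0] + rows[-1] + 1) / 2.0
    y0 = int(round(yc - h / 2.0))
    return ROI(x0=int(cols[0]), x1=int(cols[-1] + 1), y0=y0, y1=y0 + h)


def breakpoint_edges(width: int, n_bins: int = N_BREAKPOINTS) -> np.ndarray:
    """Column offsets (length n_bins+1) splitting *width* columns into
    contiguous near-equal groups.

    The proportional rule ``edges[i] = floor(i·width/n_bins)`` spreads the
    leftover columns evenly, so bin k always covers the horizontal interval
    [k/n, (k+1)/n) of the ROI — a wider-bins-first split would skew the
    spatial mapping whenever width is not a multiple of n_bins.
    """
    return (np.arange(n_bins + 1) * width) // n_bins


def _column_bin_index(width: int, n_bins: int = N_BREAKPOINTS) -> np.ndarray:
    """Breakpoint index (0-based) of each ROI column."""
    edges = breakpoint_edges(width, n_bins)
    return np.repeat(np.arange(n_bins), np.diff(edges))


def bin_breakpoints(
    roi: ROI,
    mask: BinaryMask,
    values: np.ndarray,
    n_bins: int = N_BREAKPOINTS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-breakpoint mean/SD/count of *values* over foreground ROI pixels.

    ROI columns are partitioned into ``n_bins`` contiguous near-equal groups.
    Bins containing no foreground pixel get their mean linearly interpolated
    from the nearest non-empty bins and are flagged with n = 0.
    """
    if roi.width < n_bins:
        raise ProfileError(
            f"ROI width {roi.width} px is below the {n_bins} breakpoints; "
            "use a higher-resolution input image"
        )
    sub_vals = np.asarray(values, dtype=float)[roi.y0 : roi.y1, roi.x0 : roi.x1]
    sub_mask = mask.values[roi.y0 : roi.y1, roi.x0 : roi.x1]
    ok = sub_mask & np.isfinite(sub_vals)
    bin_of_col = _column_bin_index(roi.width, n_bins)

    mean = np.full(n_bins, np.nan)
    sd = np.zeros(n_bins)
    n = np.zeros(n_bins, dtype=int)
    for i in range(n_bins):
        cols = bin_of_col == i
        v = sub_vals[:, cols][ok[:, cols]]
        n[i] = v.size
        if v.size:
            mean[i] = v.mean()
            sd[i] = v.std()  # pixel-level spread within the bin
    empty = n == 0
    if empty.all():
        raise ProfileError("no foreground pixels inside the ROI")
    if empty.any():
        idx = np.arange(n_bins)
        mean[empty] = np.interp(idx[empty], idx[~empty], mean[~empty])
    return mean, sd, n


def raw_profile(
    img: np.ndarray,
    masking_cfg: MaskingConfig | None = None,
    pigment_color: SRGBColor | str = DEFAULT_PIGMENT_COLOR,
) -> np.ndarray:
    """200-bin means of *raw* pigmentation P (no baseline normalization).

    This is the quantity averaged across unpigmented wild-type plates when
    building a baseline distribution.
    """
    mask = make_patch_mask(img, masking_cfg)
    p = pixel_pigmentation(img, mask, pigment_color)
    roi = select_roi(mask)
    mean, _, _ = bin_breakpoints(roi, mask, p)
    return mean


def compute_baseline(unpigmented_profiles: "list[np.ndarray]") -> BaselineDistribution:
    """Average per-bin raw pigmentation across unpigmented-patch profiles.

    ``Pb_i`` is the mean over images of each image's bin-i mean; ``Pb_min``
    is the minimum over bins.
    """
    if not unpigmented_profiles:
        raise ValueError("need at least one unpigmented profile")
    arr = np.asarray(unpigmented_profiles, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_BREAKPOINTS:
        raise ValueError(f"each profile must have exactly {N_BREAKPOINTS} bins")
    return BaselineDistribution(pb=arr.mean(axis=0), n_images=arr.shape[0])


def baseline_from_images(
    images: "list[np.ndarray]",
    masking_cfg: MaskingConfig | None = None,
    pigment_color: SRGBColor | str = DEFAULT_PIGMENT_COLOR,
) -> BaselineDistribution:
    """Build a baseline distribution directly from unpigmented plate images."""
    return compute_baseline([raw_profile(im, masking_cfg, pigment_color) for im in images])


def effective_pigmentation(P: "np.ndarray | float", pb_min: float) -> "np.ndarray | float":
    """Rescale raw pigmentation so the baseline minimum maps to zero.

    Piecewise: 0 below pb_min, else (P − pb_min)/(1 − pb_min).
    """
    if pb_min >= 1.0:
        raise ValueError(f"baseline minimum {pb_min} must be below 1")
    P_arr = np.asarray(P, dtype=float)
    pe = np.where(P_arr < pb_min, 0.0, (P_arr - pb_min) / (1.0 - pb_min))
    return float(pe) if np.isscalar(P) else pe


def corrected_profile(
    pe_raster: np.ndarray,
    roi: ROI,
    mask: BinaryMask,
    baseline: BaselineDistribution,
    orientation: str = "interaction-first",
) -> PigmentationProfile:
    """Apply the per-breakpoint edge-shading correction and bin the result.

    Per pixel, ``P_f = P_e − (Pb_i − Pb_min)/(1 − Pb_min)`` with i the
    breakpoint of the pixel's column, floored at 0; then averaged per
    breakpoint.  The correction term is the baseline excess of that
    breakpoint expressed in effective-pigmentation units, so a patch whose
    raw pigmentation matches the baseline everywhere corrects to zero.
    """
    correction = (baseline.pb - baseline.pb_min) / (1.0 - baseline.pb_min)
    bin_of_col = _column_bin_index(roi.width)
    pf = np.array(pe_raster, dtype=float)
    sub = pf[roi.y0 : roi.y1, roi.x0 : roi.x1]
    sub -= correction[bin_of_col][np.newaxis, :]
    np.clip(sub, 0.0, None, out=sub)
    pf[roi.y0 : roi.y1, roi.x0 : roi.x1] = sub
    mean, sd, n = bin_breakpoints(roi, mask, pf)
    return PigmentationProfile(mean=mean, sd=sd, n_pixels=n, orientation=orientation)


def extract_profile(
    img: np.ndarray,
    baseline: BaselineDistribution | None = None,
    masking_cfg: MaskingConfig | None = None,
    pigment_color: SRGBColor | str = DEFAULT_PIGMENT_COLOR,
    flip: bool = False,
) -> PigmentationProfile:
    """Full image → profile pipeline for one plate photograph.

    Composition of masking, per-pixel pigmentation, ROI selection, baseline
    rescaling and spatial correction.  ``flip=True`` mirrors the image first
    so that bin 1 always corresponds to the edge facing the interacting
    strain.
    """
    if baseline is None:
        baseline = default_baseline()
    if flip:
        img = np.ascontiguousarray(np.asarray(img)[:, ::-1])
    mask = make_patch_mask(img, masking_cfg)
    p = pixel_pigmentation(img, mask, pigment_color)
    roi = select_roi(mask)
    pe = effective_pigmentation(p, baseline.pb_min)
    return corrected_profile(pe, roi, mask, baseline)
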