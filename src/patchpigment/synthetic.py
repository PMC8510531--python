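"""Synthetic plate images and DE tables with known ground truth.

Plate generator
---------------
A plate is an elliptical colony patch on uniform agar.  Inside the patch,
pixel color is a convex blend — in linear-light sRGB, so mixing is
physically sensible — of an unpigmented colony base color and the red
pigment color, weighted by a 1-D pigment profile function of the normalized
horizontal position across the patch.  On top of that the generator adds:

* a multiplicative radial vignette darkening the patch toward its edges
  (patches are three-dimensional and their rims sit in shadow);
* small agar-colored interior holes (glossy/unpigmented spots);
* small colony-colored specks on the agar (bubbles, imperfections);
* Gaussian per-channel pixel noise.

Each speck and hole is individually smaller than the masking stage's
correction thresholds, so the ground-truth patch footprint is exactly
recoverable by the mask pipeline.  The generator returns the rendered image
together with the footprint and the profile function sampled at the 200
breakpoint centers.

DE-table generator
------------------
Per condition, null genes draw log2FC from a normal distribution with
uniform p-values; planted genes are shifted by their effect size and get
near-zero p-values.  The truth record lists the planted ids per condition.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .colorspace import SRGBColor
from .expression import DETable
from .masking import DEFAULT_HOLE_FRACTION, DEFAULT_NOISE_FRACTION
from .profiling import N_BREAKPOINTS

__all__ = [
    "PlateSimParams",
    "PlateTruth",
    "generate_plate",
    "flat_profile",
    "step_profile",
    "ramp_profile",
    "first_quarter_peak",
    "DESimParams",
    "PlantedSet",
    "DETruth",
    "generate_de_tables",
]


# ---------------------------------------------------------------------------
# plate images


def flat_profile(level: float = 0.0) -> Callable[[np.ndarray], np.ndarray]:
    """Constant pigment weight (0 = fully unpigmented patch)."""

    def f(x: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(x, dtype=float), level)

    return f


def step_profile(x0: float = 0.25, lo: float = 0.05, hi: float = 0.9) -> Callable:
    """Pigment weight hi left of x0, lo right of it."""

    def f(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(x < x0, hi, lo)

    return f


def ramp_profile(lo: float = 0.0, hi: float = 0.9) -> Callable:
    """Pigment weight decreasing linearly from hi at x=0 to lo at x=1."""

    def f(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return hi + (lo - hi) * x

    return f


def first_quarter_peak(peak: float = 0.95, mid: float = 0.55, tail: float = 0.1) -> Callable:
    """Intense pigmentation in the first quarter of the patch, lighter and
    declining across the rest — the wild-type interaction pattern."""

    def f(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        decline = mid + (tail - mid) * (x - 0.25) / 0.75
        return np.where(x < 0.25, peak, decline)

    return f


def _srgb_to_linear(rgb01: np.ndarray) -> np.ndarray:
    rgb01 = np.asarray(rgb01, dtype=float)
    return np.where(rgb01 <= 0.04045, rgb01 / 12.92, ((rgb01 + 0.055) / 1.055) ** 2.4)


def _linear_to_srgb(lin: np.ndarray) -> np.ndarray:
    lin = np.clip(lin, 0.0, 1.0)
    return np.where(lin <= 0.0031308, lin * 12.92, 1.055 * lin ** (1 / 2.4) - 0.055)


@dataclass
class PlateSimParams:
    """Knobs of the plate generator; the defaults describe a 480×360 plate
    with a 300×180 px elliptical patch on dark agar."""

    height: int = 360
    width: int = 480
    agar_color: str = "33393E"
    patch_center: tuple[int, int] = (180, 240)  # (row, col)
    patch_axes: tuple[int, int] = (90, 150)  # (semi-height, semi-width), px
    colony_base_color: str = "C8C2B8"
    pigment_color: str = "803D33"
    profile_fn: Callable[[np.ndarray], np.ndarray] = field(default_factory=flat_profile)
    speck_count: int = 5
    speck_size: int = 12  # pixels per speck (area)
    hole_count: int = 3
    hole_size: int = 20  # pixels per hole (area)
    vignette_strength: float = 0.25
    pixel_noise_sd: float = 2.0  # 8-bit channel units
    seed: int = 0

    def __post_init__(self) -> None:
        cy, cx = self.patch_center
        by, bx = self.patch_axes
        if cy - by < 0 or cy + by >= self.height or cx - bx < 0 or cx + bx >= self.width:
            raise ValueError("patch ellipse exceeds image bounds")
        total = self.height * self.width
        if self.speck_size >= DEFAULT_NOISE_FRACTION * total:
            raise ValueError("specks must stay below the noise-removal threshold")
        if self.hole_size >= DEFAULT_HOLE_FRACTION * total:
            raise ValueError("holes must stay below the hole-fill threshold")


@dataclass
class PlateTruth:
    """Ground truth accompanying a generated plate.

    ``weights`` is the raw pigment blend weight at the 200 breakpoint
    centers; ``profile`` is the effective pigmentation those blend weights
    actually paint into the pixels (weight mapped through the linear-light
    blend, the sRGB→Lab conversion and the baseline rescaling, with the
    unpigmented base color as the floor) — i.e. the pigmentation profile a
    perfect, shading-free measurement of this plate would report.
    """

    footprint: np.ndarray  # H×W bool, the true patch (holes included)
    profile: np.ndarray  # expected effective pigmentation per breakpoint
    weights: np.ndarray  # profile_fn at the 200 breakpoint centers
    params: PlateSimParams


def _disc(shape: tuple[int, int], center: tuple[float, float], area: int) -> np.ndarray:
    r = max(1.0, np.sqrt(area / np.pi))
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r**2


def generate_plate(params: PlateSimParams) -> tuple[np.ndarray, PlateTruth]:
    """Render a synthetic plate image and its ground truth."""
    rng = np.random.default_rng(params.seed)
    H, W = params.height, params.width
    cy, cx = params.patch_center
    by, bx = params.patch_axes

    yy, xx = np.ogrid[:H, :W]
    r2 = ((yy - cy) / by) ** 2 + ((xx - cx) / bx) ** 2
    footprint = r2 <= 1.0

    # pigment weight from the 1-D profile of normalized horizontal position
    u = np.clip((np.arange(W) - (cx - bx)) / (2.0 * bx), 0.0, 1.0)
    w_col = np.clip(np.asarray(params.profile_fn(u), dtype=float), 0.0, 1.0)
    w = np.broadcast_to(w_col, (H, W))

    agar = _srgb_to_linear(SRGBColor.from_hex(params.agar_color).as_float())
    base = _srgb_to_linear(SRGBColor.from_hex(params.colony_base_color).as_float())
    pig = _srgb_to_linear(SRGBColor.from_hex(params.pigment_color).as_float())

    lin = np.empty((H, W, 3))
    lin[...] = agar
    patch_lin = (1.0 - w[..., None]) * base + w[..., None] * pig
    # radial luminance falloff toward the patch rim
    vignette = 1.0 - params.vignette_strength * np.clip(r2, 0.0, 1.0) ** 2
    patch_lin = patch_lin * vignette[..., None]
    lin[footprint] = patch_lin[footprint]

    # interior holes: agar-colored spots well inside the patch
    for _ in range(params.hole_count):
        for _attempt in range(100):
            hy = cy + (rng.uniform(-0.6, 0.6)) * by
            hx = cx + (rng.uniform(-0.6, 0.6)) * bx
            if ((hy - cy) / by) ** 2 + ((hx - cx) / bx) ** 2 < 0.5:
                break
        lin[_disc((H, W), (hy, hx), params.hole_size)] = agar

    # specks: colony-colored droplets on the agar, clear of the patch
    for _ in range(params.speck_count):
        for _attempt in range(200):
            sy = rng.uniform(0.05 * H, 0.95 * H)
            sx = rng.uniform(0.05 * W, 0.95 * W)
            if ((sy - cy) / by) ** 2 + ((sx - cx) / bx) ** 2 > 1.5:
                break
        lin[_disc((H, W), (sy, sx), params.speck_size)] = base

    img = _linear_to_srgb(lin) * 255.0
    if params.pixel_noise_sd > 0:
        img = img + rng.normal(0.0, params.pixel_noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    centers = (np.arange(N_BREAKPOINTS) + 0.5) / N_BREAKPOINTS
    weights = np.clip(np.asarray(params.profile_fn(centers), dtype=float), 0.0, 1.0)
    truth_profile = _expected_pigmentation(weights, base, pig, params.pigment_color)
    return img, PlateTruth(
        footprint=footprint, profile=truth_profile, weights=weights, params=params
    )


def _expected_pigmentation(
    weights: np.ndarray, base_lin: np.ndarray, pig_lin: np.ndarray, pigment_hex: str
) -> np.ndarray:
    """Effective pigmentation a noiseless, shading-free blend would score.

    Maps each blend weight through the same rendering chain the pixels go
    through (linear-light blend → sRGB → normalized Lab → p = 1 − d_s),
    then rescales with the unpigmented base color's pigmentation as the
    baseline floor.
    """
    from skimage import color as _skcolor

    from .colorspace import AB_SCALE, L_SCALE, LabColor, normalized_distance, srgb_to_lab

    target = srgb_to_lab(pigment_hex)
    blends = (1.0 - weights[:, None]) * base_lin + weights[:, None] * pig_lin
    rgb = _linear_to_srgb(blends).reshape(-1, 1, 3)
    lab = _skcolor.rgb2lab(rgb).reshape(-1, 3)
    p = np.array(
        [
            1.0 - normalized_distance(LabColor(L / L_SCALE, a / AB_SCALE, b / AB_SCALE), target)
            for L, a, b in lab
        ]
    )
    base_lab = _skcolor.rgb2lab(_linear_to_srgb(base_lin).reshape(1, 1, 3)).reshape(3)
    p0 = 1.0 - normalized_distance(
        LabColor(base_lab[0] / L_SCALE, base_lab[1] / AB_SCALE, base_lab[2] / AB_SCALE), target
    )
    return np.clip((p - p0) / (1.0 - p0), 0.0, 1.0)


# ---------------------------------------------------------------------------
# DE tables


@dataclass(frozen=True)
class PlantedSet:
    """A group of truly regulated genes planted into the null background."""

    name: str
    n_genes: int
    effect: float  # log2FC shift added to the null draw
    conditions: tuple[int, ...] | None = None  # None = planted in every condition


@dataclass
class DESimParams:
    n_genes: int = 8000
    null_mean: float = 0.0
    null_sd: float = 1.0
    planted: Sequence[PlantedSet] = ()
    n_conditions: int = 4
    planted_p_max: float = 1e-4  # planted p-values drawn uniformly below this
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(ps.n_genes for ps in self.planted) > self.n_genes:
            raise ValueError("planted sets exceed the gene universe")


@dataclass
class DETruth:
    planted_ids: dict[str, tuple[str, ...]]  # set name -> gene ids
    planted_by_condition: dict[int, set]  # condition index -> planted gene ids


def generate_de_tables(params: DESimParams) -> tuple[list[DETable], DETruth]:
    """Simulate one DE table per condition plus the planting truth record.

    Planted sets occupy disjoint blocks at the start of the gene universe;
    gene ids are ``G000001`` upward.
    """
    rng = np.random.default_rng(params.seed)
    gene_ids = np.array([f"G{i + 1:06d}" for i in range(params.n_genes)])

    planted_ids: dict[str, tuple[str, ...]] = {}
    planted_by_condition: dict[int, set] = {c: set() for c in range(params.n_conditions)}
    cursor = 0
    plan: list[tuple[np.ndarray, PlantedSet]] = []
    for ps in params.planted:
        idx = np.arange(cursor, cursor + ps.n_genes)
        cursor += ps.n_genes
        planted_ids[ps.name] = tuple(gene_ids[idx])
        conds = range(params.n_conditions) if ps.conditions is None else ps.conditions
        for c in conds:
            planted_by_condition[c].update(gene_ids[idx])
        plan.append((idx, ps))

    tables: list[DETable] = []
    for c in range(params.n_conditions):
        lfc = rng.normal(params.null_mean, params.null_sd, size=params.n_genes)
        pval = rng.uniform(0.0, 1.0, size=params.n_genes)
        for idx, ps in plan:
            if ps.conditions is None or c in ps.conditions:
                lfc[idx] += ps.effect
                pval[idx] = rng.uniform(0.0, params.planted_p_max, size=idx.size)
        frame = pd.DataFrame({"gene_id": gene_ids, "log2fc": lfc, "pvalue": pval})
        tables.append(DETable(frame=frame, comparison_label=f"condition{c + 1}"))
    return tables, DETruth(planted_ids=planted_ids, planted_by_condition=planted_by_condition)
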