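"""Profiling tests: pigmentation raster, ROI, binning, baseline, extraction."""

from __future__ import annotations

import numpy as np
import pytest

from patchpigment.colorspace import SRGBColor
from patchpigment.errors import ProfileError
from patchpigment.masking import BinaryMask
from patchpigment.profiling import (
    DEFAULT_PB_MIN,
    N_BREAKPOINTS,
    ROI,
    BaselineDistribution,
    bin_breakpoints,
    breakpoint_edges,
    compute_baseline,
    corrected_profile,
    default_baseline,
    effective_pigmentation,
    extract_profile,
    pixel_pigmentation,
    select_roi,
)
from patchpigment.synthetic import (
    PlateSimParams,
    first_quarter_peak,
    flat_profile,
    generate_plate,
    ramp_profile,
)


def _rect_mask(h, w, y0, y1, x0, x1):
    values = np.zeros((h, w), dtype=bool)
    values[y0:y1, x0:x1] = True
    return BinaryMask(values)


# --- pixel pigmentation -----------------------------------------------------


def test_pigment_colored_pixel_scores_one():
    img = np.empty((2, 2, 3), dtype=np.uint8)
    img[...] = (0x80, 0x3D, 0x33)
    mask = BinaryMask(np.ones((2, 2), dtype=bool))
    p = pixel_pigmentation(img, mask)
    assert p == pytest.approx(np.ones((2, 2)))


def test_background_pixels_are_nan_and_shape_mismatch_raises():
    img = np.zeros((3, 3, 3), dtype=np.uint8)
    mask = BinaryMask(np.eye(3, dtype=bool))
    p = pixel_pigmentation(img, mask)
    assert np.isnan(p[0, 1])
    assert np.isfinite(p[0, 0])
    with pytest.raises(ValueError, match="shape"):
        pixel_pigmentation(img, BinaryMask(np.ones((2, 2), dtype=bool)))


def test_gradient_strip_pigmentation_increases_toward_pigment_end():
    agar = SRGBColor.from_hex("33393E").as_float()
    pig = SRGBColor.from_hex("803D33").as_float()
    w = np.linspace(0, 1, 50)
    strip = ((1 - w[None, :, None]) * agar + w[None, :, None] * pig) * 255
    img = np.round(strip).astype(np.uint8).repeat(2, axis=0)
    mask = BinaryMask(np.ones((2, 50), dtype=bool))
    p = pixel_pigmentation(img, mask)
    assert np.all(np.diff(p[0]) > -1e-6)
    assert p[0, -1] > p[0, 0] + 0.2


# --- ROI selection ----------------------------------------------------------


def test_roi_height_is_20_percent_of_patch_height():
    mask = _rect_mask(200, 400, 40, 140, 50, 350)  # patch height 100
    roi = select_roi(mask)
    assert roi.height == 20
    assert (roi.x0, roi.x1) == (50, 350)
    # vertically centered on the patch midpoint (row 90)
    assert (roi.y0 + roi.y1) / 2 == pytest.approx(90, abs=1)


def test_roi_height_rounds_for_odd_patch_heights():
    # circular patch of diameter 101 -> round(20.2) = 20
    values = np.zeros((150, 150), dtype=bool)
    yy, xx = np.ogrid[:150, :150]
    values[(yy - 75) ** 2 + (xx - 75) ** 2 <= 50.4**2] = True
    roi = select_roi(BinaryMask(values))
    assert roi.height == 20


def test_degenerate_patch_raises():
    with pytest.raises(ProfileError, match="degenerate"):
        select_roi(_rect_mask(50, 300, 10, 13, 0, 300))


def test_roi_inside_patch_bounding_box_for_random_synthetic_patches(rng):
    for seed in rng.integers(0, 10_000, size=10):
        img, truth = generate_plate(
            PlateSimParams(profile_fn=flat_profile(), hole_count=0, seed=int(seed))
        )
        rows = np.flatnonzero(truth.footprint.any(axis=1))
        cols = np.flatnonzero(truth.footprint.any(axis=0))
        from patchpigment.masking import make_patch_mask

        roi = select_roi(make_patch_mask(img))
        assert rows[0] <= roi.y0 < roi.y1 <= rows[-1] + 1
        assert cols[0] <= roi.x0 < roi.x1 <= cols[-1] + 1


# --- breakpoint binning -----------------------------------------------------


def test_constant_raster_gives_constant_bins():
    mask = _rect_mask(40, 400, 0, 40, 0, 400)
    roi = ROI(0, 400, 10, 30)
    values = np.full((40, 400), 0.37)
    mean, sd, n = bin_breakpoints(roi, mask, values)
    assert mean == pytest.approx(np.full(N_BREAKPOINTS, 0.37))
    assert sd == pytest.approx(np.zeros(N_BREAKPOINTS))
    assert (n == 40).all()  # 2 columns × 20 rows per bin


def test_width_400_gives_two_columns_per_bin():
    edges = breakpoint_edges(400)
    assert (np.diff(edges) == 2).all()


def test_partition_is_contiguous_near_equal_and_spatially_proportional():
    for width in (301, 555, 1024):
        edges = breakpoint_edges(width)
        sizes = np.diff(edges)
        assert sizes.sum() == width
        assert sizes.min() >= width // N_BREAKPOINTS
        assert sizes.max() <= width // N_BREAKPOINTS + 1
        # bin k covers the horizontal interval [k/200, (k+1)/200)
        mids = (edges[:-1] + edges[1:]) / 2 / width
        assert np.abs(mids - (np.arange(N_BREAKPOINTS) + 0.5) / N_BREAKPOINTS).max() < 1 / N_BREAKPOINTS


def test_step_raster_matches_brute_force_column_averaging(rng):
    h, w = 30, 517
    mask = _rect_mask(h, w, 0, h, 0, w)
    roi = ROI(0, w, 5, 25)
    values = rng.uniform(size=(h, w))
    mean, sd, n = bin_breakpoints(roi, mask, values)
    edges = breakpoint_edges(w)
    for i in range(0, N_BREAKPOINTS, 17):
        block = values[5:25, edges[i] : edges[i + 1]]
        assert mean[i] == pytest.approx(block.mean())
        assert sd[i] == pytest.approx(block.std())
        assert n[i] == block.size


def test_half_step_lands_in_bins_1_to_100():
    mask = _rect_mask(20, 400, 0, 20, 0, 400)
    roi = ROI(0, 400, 0, 20)
    values = np.zeros((20, 400))
    values[:, 200:] = 1.0
    mean, _, _ = bin_breakpoints(roi, mask, values)
    assert mean[:100] == pytest.approx(np.zeros(100))
    assert mean[100:] == pytest.approx(np.ones(100))


def test_narrow_roi_raises_advice():
    mask = _rect_mask(20, 150, 0, 20, 0, 150)
    with pytest.raises(ProfileError, match="resolution"):
        bin_breakpoints(ROI(0, 150, 0, 20), mask, np.zeros((20, 150)))


def test_empty_bins_are_interpolated_and_flagged():
    mask = _rect_mask(20, 400, 0, 20, 0, 400)
    mask.values[:, 100:104] = False  # knock out bins 51-52 entirely
    roi = ROI(0, 400, 0, 20)
    values = np.tile(np.linspace(0, 1, 400), (20, 1))
    mean, sd, n = bin_breakpoints(roi, mask, values)
    assert (n[50:52] == 0).all()
    assert np.isfinite(mean).all()
    assert mean[49] < mean[50] < mean[51] < mean[52]


# --- baseline ---------------------------------------------------------------


def test_single_profile_baseline_is_that_profile(rng):
    prof = rng.uniform(0.3, 0.5, N_BREAKPOINTS)
    b = compute_baseline([prof])
    assert b.pb == pytest.approx(prof)
    assert b.pb_min == pytest.approx(prof.min())


def test_two_constant_profiles_average():
    b = compute_baseline([np.full(N_BREAKPOINTS, 0.3), np.full(N_BREAKPOINTS, 0.4)])
    assert b.pb == pytest.approx(np.full(N_BREAKPOINTS, 0.35))
    assert b.pb_min == pytest.approx(0.35)


def test_wrong_length_profile_rejected():
    with pytest.raises(ValueError):
        compute_baseline([np.zeros(100)])


def test_recomputed_baseline_minimum_near_generator_floor(baseline12):
    # unpigmented base color C8C2B8 scores p ≈ 0.349 against the pigment target
    assert baseline12.pb_min == pytest.approx(0.349, abs=0.05)
    assert baseline12.n_images == 12


def test_default_baseline_is_flat_at_packaged_minimum():
    b = default_baseline()
    assert b.pb_min == DEFAULT_PB_MIN == 0.342
    assert (b.pb == DEFAULT_PB_MIN).all()


# --- effective pigmentation -------------------------------------------------


def test_effective_pigmentation_piecewise_rule():
    assert effective_pigmentation(1.0, 0.342) == pytest.approx(1.0)
    assert effective_pigmentation(0.342, 0.342) == 0.0
    assert effective_pigmentation(0.2, 0.342) == 0.0
    # (0.671 - 0.342) / (1 - 0.342) = 0.5 with the packaged minimum
    assert effective_pigmentation(0.671, 0.342) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        effective_pigmentation(0.5, 1.0)


# --- corrected profile & extraction ----------------------------------------


def test_flat_baseline_correction_is_identity():
    mask = _rect_mask(40, 400, 0, 40, 0, 400)
    roi = ROI(0, 400, 10, 30)
    pe = np.random.default_rng(0).uniform(0.2, 0.8, size=(40, 400))
    flat = BaselineDistribution(pb=np.full(N_BREAKPOINTS, 0.342))
    prof = corrected_profile(pe, roi, mask, flat)
    mean, sd, n = bin_breakpoints(roi, mask, pe)
    assert prof.mean == pytest.approx(mean)
    assert prof.sd == pytest.approx(sd)


def test_unpigmented_plate_corrects_to_near_zero(baseline12):
    img, _ = generate_plate(PlateSimParams(profile_fn=flat_profile(), hole_count=0, seed=500))
    prof = extract_profile(img, baseline12)
    assert prof.mean.max() <= 0.02


def test_vignette_correction_flattens_edge_artifacts(baseline12):
    img, _ = generate_plate(PlateSimParams(profile_fn=flat_profile(), hole_count=0, seed=501))
    corrected = extract_profile(img, baseline12)
    uncorrected = extract_profile(img, default_baseline(baseline12.pb_min))
    assert corrected.mean.max() - corrected.mean.min() < 0.05
    # without the spatial term, shading shows up at the patch rim
    assert uncorrected.mean.max() > 0.08


def test_first_quarter_peak_profile_peaks_in_first_quarter(baseline12):
    img, _ = generate_plate(
        PlateSimParams(profile_fn=first_quarter_peak(), hole_count=0, seed=502)
    )
    prof = extract_profile(img, baseline12)
    assert int(prof.mean.argmax()) + 1 <= 50
    assert prof.mean.max() > 0.5  # easily visible pigmentation


def test_isolated_wild_type_profile_stays_below_visibility_threshold(baseline12):
    img, _ = generate_plate(PlateSimParams(profile_fn=flat_profile(), hole_count=0, seed=503))
    prof = extract_profile(img, baseline12)
    assert (prof.mean < 0.5).all()


def test_mirrored_image_with_flip_gives_identical_profile(baseline12):
    img, _ = generate_plate(
        PlateSimParams(profile_fn=ramp_profile(), hole_count=0, seed=504)
    )
    direct = extract_profile(img, baseline12)
    mirrored = extract_profile(img[:, ::-1], baseline12, flip=True)
    assert mirrored.mean == pytest.approx(direct.mean)
    assert mirrored.sd == pytest.approx(direct.sd)


def test_extraction_is_deterministic(baseline12):
    img, _ = generate_plate(PlateSimParams(profile_fn=ramp_profile(), hole_count=0, seed=505))
    a = extract_profile(img, baseline12)
    b = extract_profile(img.copy(), baseline12)
    assert np.array_equal(a.mean, b.mean) and np.array_equal(a.sd, b.sd)


def test_profile_bounded_and_pf_not_above_pe(baseline12):
    img, _ = generate_plate(
        PlateSimParams(profile_fn=first_quarter_peak(), hole_count=0, seed=506)
    )
    corrected = extract_profile(img, baseline12)
    uncorrected = extract_profile(img, default_baseline(baseline12.pb_min))
    assert (corrected.mean >= 0).all() and (corrected.mean <= 1).all()
    assert (corrected.mean <= uncorrected.mean + 1e-9).all()


def test_upscaling_changes_bin_means_only_slightly(baseline12):
    img, _ = generate_plate(
        PlateSimParams(profile_fn=ramp_profile(), hole_count=0, pixel_noise_sd=0, seed=507)
    )
    big = img.repeat(2, axis=0).repeat(2, axis=1)
    a = extract_profile(img, baseline12)
    b = extract_profile(big, baseline12)
    assert np.abs(a.mean - b.mean).max() < 0.02
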