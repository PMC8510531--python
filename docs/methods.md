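# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic data used to validate them, and the
design choices made where the method description left room.

## Color model

Pixels are converted from 8-bit sRGB (D65 white point, 2° observer,
standard transfer function — the dominant convention for consumer camera
imagery) to CIELAB, then rescaled into a *normalized* frame:

    λ = L*/100,  α = a*/255,  β = b*/255.

This puts the space inside a sphere of diameter 1 whose center (0.5, 0, 0)
is mid-gray (L* = 50, a* = b* = 0), reconciling a unit-diameter sphere with
a radius of 0.5. The divisor 255 for the opponent axes is a convention
choice (a*/b* span roughly −128..127 in the sRGB gamut); it is exposed as
`colorspace.AB_SCALE` should anyone need a different frame.

Distance between colors is Euclidean in (λ, α, β). For a target color *c*
the maximum attainable distance is d_max(c) = ‖c − center‖ + 0.5 (so a
surface color has d_max = 1, the center itself 0.5), and the normalized
distance is d_s = d/d_max. Strongly saturated colors can poke slightly
outside the sphere, so d_s is clamped into [0, 1]. CIEDE2000 and ICC
profile handling are deliberately out of scope: the method is a ratio
instrument, not an absolute colorimeter.

## Masking

Background classification compares every pixel to a fixed agar color
(default `33393E`, a dark blue-gray averaged from plate backgrounds);
pixels with d_s ≤ 0.15 are agar. Two corrections follow, both driven by
connected-component size as a fraction of the *total image* pixel count:

* foreground components below 2% are removed (bubbles, specks);
* background components that do not touch the image border and are below
  20% are filled (holes within the patch).

Thresholds are strict: a component of exactly the threshold size is left
alone. Foreground uses 8-connectivity and background the dual
4-connectivity, the standard pairing that avoids topological paradoxes;
both are configurable. Corrections run in the order stated (denoise, then
fill); both operations are idempotent and the mask must end as exactly one
component or the stage raises. An alternative to the fixed agar color —
averaging a user-specified background region per image
(`sample_background_color`) — is provided for plates photographed under
different conditions.

## Profiling and baseline correction

Foreground pixels score p = 1 − d_s against the red pigment target
(default `803D33`, averaged from strongly pigmented patches; at the assay's
pH both actinorhodin and prodiginines read as red, so the score quantifies
combined red pigmentation only).

The region of interest is a rectangle spanning the patch's horizontal
bounding box, vertically centered on the bounding box midpoint, with height
round(0.20 × patch height). Its columns are partitioned into 200
breakpoints by the proportional rule edges[i] = floor(i·W/200), which keeps
groups contiguous and near-equal *and* maps bin k to the horizontal
interval [k/200, (k+1)/200) regardless of W. (A wider-groups-first split
would skew the spatial mapping whenever W is not a multiple of 200 — a
step planted at x = 0.25 of a 301-px ROI would land 12 bins early.) ROIs
narrower than 200 columns are rejected with advice to use
higher-resolution input. Bins with no foreground pixels (possible for
concave patches) are linearly interpolated from their nearest non-empty
neighbors and flagged with n_pixels = 0.

Unpigmented patches do not score p = 0 — lightness and shading contribute
— so raw pigmentation is normalized against a baseline distribution Pb:
the per-breakpoint mean of raw pigmentation over unpigmented isolated
patches (12 in the reference design). With Pb_min = min_i Pb_i:

    P_e = 0                         if P < Pb_min
    P_e = (P − Pb_min)/(1 − Pb_min) otherwise

and, per pixel in breakpoint i,

    P_f = max(0, P_e − (Pb_i − Pb_min)/(1 − Pb_min)).

The correction term is Pb's excess over its minimum *expressed in the same
rescaled units as P_e*. Subtracting the raw difference Pb_i − Pb_min
instead would under-correct shading by the factor (1 − Pb_min), leaving an
unpigmented patch with a residual of roughly (Pb_i − Pb_min)·Pb_min/(1 −
Pb_min) ≈ 0.06 at the rim; with the rescaled term an unpigmented patch
profiled against its own baseline corrects to ≈ 0 everywhere, which is the
stated purpose of the correction. The correction is applied per pixel
before binning; per-pixel and per-bin application give the same bin means
but different bin SDs, and the per-pixel order keeps the SD faithful to the
pixel population.

A flat packaged baseline (Pb ≡ 0.342, the reference Pb_min) is shipped for
users without their own unpigmented plates: it applies the standard P_e
threshold while contributing no spatial correction. Recomputing the
baseline from matched unpigmented images is strongly preferred and is what
the `baseline` subcommand does.

Orientation: bin 1 is the patch edge facing the interaction partner. The
`flip` option mirrors the image before any processing, so a mirrored image
with the flag set yields a bit-identical profile.

## Replicate aggregation

Profiles of replicate patches (20 per condition in the reference design)
are averaged per bin with the sample (n−1) SD. The representative
replicate minimizes the Euclidean distance between its 200 bin means and
the across-replicate mean vector, ties broken toward the lowest index.
"Similarity" was not further specified; L2 matches the Euclidean metric
used elsewhere in the analysis. Pixel-level SD (within one image's bins)
and replicate-level SD are both emitted, as they answer different
questions.

## Expression filters

DE tables carry (gene_id, log2fc, pvalue[, padj]) per comparison. Rules:

* **2-SD rule** — flag genes with |log2FC − mean| > 2·SD and p < α
  (default 0.05); mean and SD are per-table (each comparison defines its
  own distribution), computed with the sample SD. The rule is
  shift-invariant by construction. On a pure null (log2FC ~ N(0, 1),
  p ~ U(0, 1)) the expected flagged fraction is 2Φ(−2)·0.05 ≈ 0.00228,
  which the test suite verifies by Monte Carlo.
* **Fixed thresholds** — |log2FC| ≥ cutoff (boundary inclusive) and p < α;
  the conventional cutoffs 2 (4-fold) and 1.58 (3-fold) are defaults in
  the CLI and examples.
* **Venn counts** — genes flagged in exactly k / at least k of several
  conditions, over the union of gene ids; genes absent from a table count
  as unflagged there and the count of such genes is logged.
* **Cluster summaries** — mean and sample SD of log2FC over a named gene
  cluster (the cryptic lanthipeptide cluster SCO6927–SCO6938 ships as a
  built-in definition); missing genes are reported, never imputed; Welch
  two-sample t-tests compare cluster values between conditions (a
  pooled-variance option exists), with stars at p ≤ 0.05/0.01/0.001/0.0001.
* **PCA / clustering** — strains are observations, shared genes features;
  scikit-learn PCA with variance-explained percentages, scipy
  average-linkage clustering on Euclidean distances. Linkage was not
  specified; average linkage is the common default for expression heatmaps.

p-values are used as provided (the upstream differential tester's output);
no additional multiple-testing correction is layered on, and `use_padj`
switches the gates to an adjusted-p column where present.

## Synthetic data

The plate generator renders an elliptical patch on uniform agar. Within
the patch, color is a convex blend — in linear-light sRGB, so mixing is
physically sensible — of an unpigmented colony base color (`C8C2B8`, a
pale gray whose pigmentation score ≈ 0.35 places the recomputed baseline
floor near the packaged 0.342) and the pigment color, weighted by a 1-D
profile of the normalized horizontal position (flat, step, ramp, or the
first-quarter-peak shape typical of an induced interaction patch). On top:
a multiplicative radial vignette (strength 0.25) emulating the shadowed
three-dimensional rim, Gaussian channel noise (SD 2 on 8-bit channels),
agar-colored interior holes and colony-colored agar specks, each
individually below the corresponding mask-correction threshold so the
footprint is exactly recoverable. Everything is a pure function of
(params, seed).

The ground-truth profile attached to each plate is the *effective
pigmentation its pixels actually carry*: the blend weight mapped through
the same linear-blend → Lab → p → P_e chain with the base color as floor.
The raw weights are also returned. The distinction matters because the
pigmentation score is a convex function of blend weight (P_e at weight
0.25 is ≈ 0.16, not 0.25); validating recovery against the weight function
would conflate spatial fidelity with that pointwise nonlinearity, which is
instead validated directly against an independent from-scratch sRGB→CIELAB
reference converter in the test suite.

What the generator does **not** emulate: colony surface texture,
illumination gradients across the plate, camera noise correlations, or the
partner colony itself (inputs are assumed pre-cropped to one patch, as in
the reference workflow; a crop option exists on the CLI). Passing tests on
synthetic plates therefore demonstrate correctness of the measurement
chain, not robustness to every photographic artifact.

One artifact of the hole model deserves note: painted holes are literally
agar-colored, and the dark agar sits fairly close to the dark-red pigment
target (p ≈ 0.74), so once filled into the mask those pixels read as
strongly pigmented. Real in-patch holes are unpigmented colony regions, not
agar. Hole-bearing plates are therefore used to exercise masking, while
profile-accuracy experiments (baseline self-consistency, pattern recovery)
use hole-free plates with vignette, noise and specks retained.

The DE generator draws null log2FC from N(0, 1) with uniform p-values and
plants disjoint gene sets with a fixed effect shift and near-zero p-values
(uniform below 10⁻⁴), per condition or in chosen subsets; the truth record
lists planted ids per set and per condition.

## Numerical choices and degenerate inputs

* Bin SD within an image is the population SD of the bin's pixels;
  across-replicate SD uses n−1.
* round() half-even is used for the ROI height (e.g. patch height 101 →
  ROI 20).
* A patch shorter than 5 px is rejected as degenerate.
* Zero-variance DE tables flag nothing under the 2-SD rule; single-gene
  clusters report SD 0 with a warning; two identical zero-variance samples
  compare as t = 0, p = 1 rather than NaN.
* Profile extraction is fully deterministic; rerunning a pipeline on the
  same inputs produces byte-identical TSVs.

## Problem sizes used in the test suite

Synthetic plates are 480 × 360 px with a 300 × 180 px patch — enough for
the 200-breakpoint requirement with ~1.5 columns per bin. Baselines use 12
unpigmented plates and recovery experiments 20 seeded plates, matching the
reference replicate design. Null-calibration tables use 10⁵ genes; the
flood-fill oracle comparison covers every 4 × 4 mask (65,536) plus 1,000
random 32 × 32 masks.

## Known limitations

* The method quantifies combined red pigmentation; it cannot separate
  actinorhodin from prodiginine contributions, nor report absolute pigment
  concentration.
* The spatial correction removes only shading that is *reproducible across
  the baseline set* along the horizontal axis; vertical or per-image
  idiosyncratic shading is untouched.
* The fixed agar target assumes consistent plate preparation and imaging;
  the per-image background sampling helper is a partial remedy, not a
  calibration.
* The 2-SD rule adapts its cutoff to each table's spread; tables dominated
  by genuine regulation will therefore flag conservatively.
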