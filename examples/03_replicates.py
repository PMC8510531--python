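"""Average 20 replicate patches and pick the representative one.

Replicate plates of the same strain/condition vary in noise and placement;
the per-bin mean ± SD summarizes the condition and the replicate closest to
that mean is chosen as the display image.
"""

from patchpigment import (
    PlateSimParams,
    ReplicateSet,
    aggregate_profiles,
    baseline_from_images,
    extract_profile,
    first_quarter_peak,
    flat_profile,
    generate_plate,
    select_representative,
)

baseline = baseline_from_images(
    [generate_plate(PlateSimParams(profile_fn=flat_profile(), hole_count=0, seed=100 + i))[0]
     for i in range(12)]
)

profiles = []
for i in range(20):
    img, _ = generate_plate(
        PlateSimParams(profile_fn=first_quarter_peak(), hole_count=0, seed=900 + i)
    )
    profiles.append(extract_profile(img, baseline))

rs = ReplicateSet(profiles=profiles, condition_label="wt-interaction")
agg = aggregate_profiles(rs)
rep = select_representative(rs)

print(f"aggregate over n = {agg.n} replicates")
print(f"mean pigmentation, first quarter (bins 1-50):  {agg.mean[:50].mean():.3f}")
print(f"mean pigmentation, last quarter (bins 151-200): {agg.mean[150:].mean():.3f}")
print(f"median per-bin replicate SD: {sorted(agg.sd)[100]:.4f}")
print(f"representative replicate: index {rep} (seed {900 + rep})")
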