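"""Score how close colors are to the red pigment target.

Colors are compared in a normalized CIELAB frame (a unit-diameter sphere
centered on mid-gray).  The normalized distance d_s of a pixel to a target
color runs from 0 (exactly the target) to 1 (maximally different), so
1 − d_s is a natural pigmentation score.
"""

from patchpigment import lab_from_cielab, max_distance, normalized_distance, srgb_to_lab

pigment = srgb_to_lab("803D33")  # red pigment target
agar = srgb_to_lab("33393E")  # dark agar background

print(f"d_max of mid-gray target:  {max_distance(lab_from_cielab(50, 0, 0)):.3f}")
print(f"d_max of the pigment target: {max_distance(pigment):.3f}")
print(f"d_s(agar vs pigment target): {normalized_distance(agar, pigment):.3f}")
print(f"d_s(white vs pigment target): {normalized_distance(srgb_to_lab('FFFFFF'), pigment):.3f}")
print()
print("A pixel of agar color therefore scores pigmentation "
      f"p = 1 - d_s = {1 - normalized_distance(agar, pigment):.3f}; pigmented "
      "colony pixels score closer to 1, pale colony pixels near 0.35.")
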