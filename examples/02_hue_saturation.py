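"""The hue-angle / saturation colour model on its own.

Shows how mean channel intensities map to the colour wheel: the angle of
the opponent-axis vector (2R - G - B, sqrt(3)(G - B)) in degrees, and
saturation (max - min)/(max + min) x 100.  R is mRFP-LC3, G is eGFP-LC3
and B the CTSD immunolabel, so each reporter state lands on a
characteristic hue.
"""

from avhue import Subtype, classify_vesicle, compute_color, compute_hue_angle, compute_saturation
from avhue.segment import ChannelThresholds

examples = [
    ("AP  (eGFP + mRFP, yellow)", (200, 200, 5)),
    ("AL  (mRFP + CTSD, purple)", (200, 5, 200)),
    ("pa-AL (all three, white)", (200, 195, 205)),
    ("LY  (CTSD only, blue)", (5, 5, 200)),
]
thresholds = ChannelThresholds(gfp_lc3=10, rfp_lc3=10, ctsd=10)

print(f"{'vesicle':28s} {'hue (deg)':>10s} {'saturation %':>13s} {'subtype':>9s}")
for label, (r, g, b) in examples:
    color = compute_color(r, g, b, bit_depth=8)
    subtype = classify_vesicle(color, thresholds)
    hue = "undefined" if color.hue_deg != color.hue_deg else f"{color.hue_deg:.1f}"
    print(f"{label:28s} {hue:>10s} {color.saturation_pct:>13.1f} {subtype.value:>9s}")

print("\ncanonical axes: red", compute_hue_angle(1, 0, 0),
      "| yellow", compute_hue_angle(1, 1, 0),
      "| green", compute_hue_angle(0, 1, 0),
      "| blue", compute_hue_angle(0, 0, 1),
      "| magenta", compute_hue_angle(1, 0, 1))
print("saturation of (0.75, 0.25, 0.25):", compute_saturation(0.75, 0.25, 0.25))
# Yellow puncta near 60 deg are AP, magenta near 300 deg AL, blue near
# 240 deg LY; the near-achromatic triple has low saturation, the pa-AL
# ("white") signature.
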