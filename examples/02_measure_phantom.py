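"""Measure the AY profile of a synthetic phantom end to end.

Generates a noise-free phantom carrying the default pooled warp, slices it
frontally, selects the calibration slice (maximum plate extent, label 6),
fits a total-least-squares line to each plate trace and reports the angle
of each line to the body horizontal.
"""

import trochwarp as tw

phantom = tw.generate_phantom(tw.default_phantom_spec("pooled"), seed=1)
profile = tw.measure_profile(phantom)
summary = tw.summarize_profile(profile)

print("measured AY angle per layer (deg):")
for layer, angle in sorted(profile.angles_deg.items()):
    marker = "  <- calibration slice" if layer == 6 else ""
    print(f"  layer {layer:2d}: {angle:6.2f}{marker}")
print()
print(f"ventral/middle/dorsal third means: {summary.ventral_third_mean:.2f} / "
      f"{summary.middle_third_mean:.2f} / {summary.dorsal_third_mean:.2f} deg")
print(f"total decrease: {summary.total_decrease:.2f} deg; "
      f"transition zone between layers {summary.transition_pair[0]} and "
      f"{summary.transition_pair[1]}")
print()
print("With zero noise the pipeline returns the planted warp exactly, which")
print("is the round-trip property the measurement stages are tested on.")
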