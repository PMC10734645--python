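"""Full reproducible pipeline run on a small synthetic cohort.

Simulates juvenile and adult phantoms (with subject-level warp variation
and point noise), measures every AY profile, contrasts the groups with a
bootstrap, runs the force model and writes diff-stable tables plus a
markdown report into an output directory.
"""

import tempfile
from pathlib import Path

import trochwarp as tw

config = tw.RunConfig(n_juvenile=5, n_adult=5, noise_sd_mm=0.5,
                      warp_sd_deg=1.0, seed=42, bootstrap_reps=500)
out = tw.run_pipeline(config, Path(tempfile.mkdtemp()) / "run")

print("outputs:", *sorted(p.name for p in out.iterdir()), sep="\n  ")
print()
print((out / "report.md").read_text())
print("Identical config + seed reproduce these tables byte for byte.")
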