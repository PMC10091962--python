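"""Build the 3-D brain morphospace from raw morphometrics.

Simulates a six-group cohort of fish with an injected relative-brain-size
shift in one hybrid group, computes ellipsoid region volumes and pooled
allometric residuals, and shows that the group shift reappears on the first
morphospace axis.
"""

import numpy as np

from hybridspace import build_brain_morphospace, generate_morphometric_cohort

records = generate_morphometric_cohort(
    n_per_group=40, seed=1, brain_weight_offsets={"F1_P1xP2": 0.05}
)
matrix, exclusions = build_brain_morphospace(records)

print(f"individuals used: {matrix.n} (excluded: {len(exclusions.exclusions)})")
print(f"axes: {matrix.trait_names}")
print(f"pooled column means (≈0 by construction): {matrix.values.mean(axis=0).round(12)}")
for group in ("P1", "P2", "F1_P1xP2"):
    mean = matrix.group_mean(group)
    print(f"group {group:10s} axis-1 mean = {mean[0]:+.4f}")
print(
    "\nAxis 1 is the residual of log10 brain weight on log10 body length;\n"
    "the ~+0.05 mean for F1_P1xP2 recovers the injected relative-brain-size shift."
)
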