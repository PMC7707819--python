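"""Domain-averaged timecourses and condition comparisons.

Extracts the dR/R timecourse of a planted curvature domain for curved and
straight gratings, and compares the frames 9–18 window with the Wilcoxon
rank-sum test.
"""

import numpy as np

from curvmap import scenarios as sc
from curvmap.timecourses import compare_timecourses, extract_domain_timecourse

model, session = sc.domain_recovery_scenario(seed=11, n_domains=4)
dom = [d for d in model.domains if d.kind == "curvature"][0]
mask = dom.mask(model.shape)
orient = {90.0: "up", 270.0: "down", 0.0: "right", 180.0: "left"}[dom.phi_deg]

tc_curved = extract_domain_timecourse(session, mask, f"c5_{orient}")
tc_straight = extract_domain_timecourse(session, mask, "s0")

print(f"domain of {tc_curved.n_pixels} px, {tc_curved.n_trials} trials")
print("frame  curved dR/R    straight dR/R")
for f in (1, 3, 6, 9, 12, 15, 18, 20):
    print(f"{f:5d}  {tc_curved.mean[f - 1]:+.2e}    "
          f"{tc_straight.mean[f - 1]:+.2e}")
# → the curved trace dips by ~2e-4 (0.02 %) peaking 2-3 s after onset
#   (frames ~12-14 at 4 Hz); the straight trace stays near zero.

amp_c = tc_curved.window_amplitude()
amp_s = tc_straight.window_amplitude()
print(f"window (frames 9-18) amplitude: curved {amp_c:.2e}, "
      f"straight {amp_s:.2e}")
res = compare_timecourses(tc_curved, tc_straight)
print(f"Wilcoxon rank-sum on frames 9-18: p = {res['p']:.2e}")
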