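"""Simulate an imaging session and compute the curvature map.

Plants 0.2–0.5 mm curvature domains in a synthetic V4 patch, simulates a
30-trial intrinsic-signal session (0.02 % amplitudes, 4 Hz, 2 pre-stimulus
frames), and computes the pixel-wise curved-vs-straight t map:
t_i = (R̄_i1 − R̄_i2)·√N / S_i on per-trial responses
(R̄₈₋₁₆ − R̄₁₋₃)/R̄₁₋₃.
"""

import numpy as np

from curvmap import scenarios as sc

model, session = sc.domain_recovery_scenario(seed=42)
print(f"session: {session.data.shape} (condition, trial, frame, row, col)")
print(f"planted curvature domains: "
      f"{sum(d.kind == 'curvature' for d in model.domains)}")

responses = sc.trial_responses_by_condition(session)
curved = [f"c5_{o}" for o in sc.CURVE_ORIENTS]
straight = ["s0", "s45", "s90", "s135"]
t_map, p_map = sc.curvature_vs_straight_maps(responses, curved, straight)

planted = model.domain_mask("curvature")
print(f"mean t inside planted domains:  {t_map.values[planted].mean():+.2f}")
print(f"mean t outside planted domains: {t_map.values[~planted].mean():+.2f}")
print(f"p<0.01 pixel fraction outside:  {(p_map.values[~planted] < 0.01).mean():.4f}")
# → strongly negative t (darkening) inside the domains, nominal false-positive
#   rate (~1 %) outside: the contrast statistics are calibrated.

sig = (p_map.values < 0.01) & (t_map.values < 0)
dice = 2 * (sig & planted).sum() / (sig.sum() + planted.sum())
print(f"Dice(significant pixels, planted mask) = {dice:.3f}")
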