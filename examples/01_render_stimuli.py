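"""Render the curvature-grating stimulus set and check its geometry.

Builds drifting curved gratings from the ellipse displacement field
Δ(x) = a(1 − sqrt(1 − x²/b²)) and prints the properties that define the set:
the central-axis profile is one sinusoid regardless of curvature, while the
flank spatial frequency grows with the a/b ratio.
"""

import numpy as np

from curvmap.stimuli import (StimulusSpec, curvature_index,
                             curved_grating_image, render_frame,
                             scramble_stimulus)

# curvature index = long axis over short axis of the generating ellipse
print("curvature index a=2,b=1:", curvature_index(2, 1))
print("curvature index a=5,b=1:", curvature_index(5, 1))

pitch = 4.0 / 401  # odd grid: one pixel sits exactly on the central axis
low = curved_grating_image(2, "up", sf_cpd=1.0, size_deg=4.0, pixel_pitch_deg=pitch)
high = curved_grating_image(5, "up", sf_cpd=1.0, size_deg=4.0, pixel_pitch_deg=pitch)

profile_diff = np.abs(low[:, 200] - high[:, 200]).max()
print(f"central-axis profile difference (ratio 2 vs 5): {profile_diff:.2e}")
# → 0: the two stimuli are indistinguishable along the vertical midline,
#   so any differential response must come from the curved flanks.

for name, img in [("ratio 2", low), ("ratio 5", high)]:
    row = img[120]  # horizontal cut through the upper field
    center = np.diff(np.signbit(row[180:220] - 0.5)).sum()
    flank = np.diff(np.signbit(row[360:400] - 0.5)).sum()
    print(f"{name}: {center} mid-luminance crossings near the axis, "
          f"{flank} on the flank (same 0.4 deg of cut)")
# → the sharper curve packs more cycles into the flank (higher local SF).

spec = StimulusSpec("curved_grating", 5.0, "up", sf_cpd=1.0)
frame = render_frame(spec, t=0.0, pixel_pitch_deg=0.05)
scrambled = scramble_stimulus(frame, n_subunits=64, seed=0)
same = np.array_equal(np.sort(scrambled.luminance.ravel()),
                      np.sort(frame.luminance[:80, :80].ravel()))
print("64-block scramble preserves the pixel histogram exactly:", same)
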