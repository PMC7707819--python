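# Methods

## The measurement model

Intrinsic-signal optical imaging records cortical reflectance R under red
illumination while visual stimuli are shown in a block design. Neural
activation increases local deoxyhemoglobin and *darkens* the image by a
fraction of order 10⁻⁴. The package's forward model for a simulated session
is

    R(x, t) = R₀ · (1 + v(x)) · (1 − resp(x) · k(t) + d(t) + ε(x, t))

with `resp(x) ≥ 0` the pixel's tuned peak response fraction, `k` a
gamma-shaped hemodynamic kernel (shape 4, unit peak at 2.5 s — inside the
2–3 s peak-time range typical of these signals; the literature gives no
canonical kernel form, so a gamma density is used), `v` a static smoothed
"vascular" pattern (multiplicative, it cancels exactly in dR/R), `d` a slow
global sinusoidal drift with random phase per trial, and `ε` white Gaussian
pixel noise per frame.

Acquisition follows the standard timing: 4 Hz frame rate, imaging starts
0.5 s before stimulus onset (2 pre-stimulus frames), stimuli last 3.5 or
4.5 s, ≥30 trials per condition. The kernel is sampled at frame-*start*
times, so frames 1–3 (1-based, the pre-stimulus baseline window plus the
onset frame) carry exactly zero evoked signal and the per-trial response
(R̄₈₋₁₆ − R̄₁₋₃)/R̄₁₋₃ equals −resp·k̄ in the noiseless limit, where k̄ is
the kernel mean over frames 8–16 (≈0.86). This identity is asserted to
1e-12 in the tests.

### Default noise level

The default per-pixel noise SD is 1×10⁻⁴ reflectance fraction per frame —
half the nominal 2×10⁻⁴ response amplitude. The choice comes from a power
calculation, not from iterating on tests: a per-trial response map carries
noise SD σ·√(1/9 + 1/3) ≈ 0.67σ, so at 30 trials the paired
curved-vs-straight contrast (4-orientation averages on both sides) has a
core-pixel t of ≈5.5 at σ = 1×10⁻⁴, comfortably above the p < 0.01
threshold (t ≈ 2.76 at 29 df), while single pixels on single trials remain
far below detectability — the regime in which trial averaging is essential,
as in real recordings. At markedly higher noise (e.g. 5× the amplitude) the
planted architecture is undetectable *in principle* at these trial counts,
which would make parameter-recovery testing vacuous. Default drift amplitude
is 1×10⁻⁵ with a 10 s timescale; drift enters all pixels of a frame equally,
so it inflates trial-to-trial variance slightly without biasing the
per-pixel t statistics.

## Stimuli

Curvature gratings derive from the ellipse X²/a² + Y²/b² = 1 with curvature
index a/b. One half-ellipse arc becomes a displacement field
Δ(x) = a(1 − √(1 − x²/b²)) with b fixed to the aperture half-width and
a = ratio·b; a drifting grating is the sinusoid of the phase coordinate
u = y + Δ(x) (apex up; other orientations by reflection/transposition, which
the tests verify are exact dihedral symmetries of the rendered frames). Two
defining properties follow analytically and are asserted: the central-axis
profile is one sinusoid of the nominal SF for *any* ratio, and the local SF
on the flanks grows with the ratio (the apex curvature is a/b², monotone in
the ratio). Straight gratings are the ratio → 0 limit. Flashed lines render
a single contour |u| ≤ w/2 (default width 0.05°, unspecified in the source
protocols) with the vertex fixed at the stimulus center; at a 4° aperture,
high-ratio lines are cropped by the aperture edge. Scrambled controls
permute an 8×8 block grid (center-cropping to a divisible size so the pixel
multiset is preserved bit-exactly; the permutation is invertible).

Where protocols list alternatives (SF 0.5 or 1 cycles/°, temporal frequency
2 or 4 Hz), the values are constructor arguments with defaults 1 cycles/°
and 2°/s drift.

## Synthetic cortical architecture

A `CorticalModel` is the ground truth a simulated session is generated from,
and everything planted is serialized for recovery tests.

* **Orientation map** — band-pass-filtered complex white noise (annular
  Gaussian filter around wavelength Λ = 0.7 mm); the half-angle of the
  filtered field is the 180°-periodic preferred orientation and its zeros
  are pinwheels. Ground-truth pinwheel centers are recorded with the same
  plaquette-winding rule the detector uses (at zero smoothing on this
  noiseless map); a brute-force loop oracle in the tests checks the winding
  computation independently.
* **Bands** — alternating orientation/color stripes (period 1.8 mm,
  orientation fraction 0.6 by default). All functional domains are placed
  fully inside orientation bands, matching the observation that curvature
  domains fall within orientation bands.
* **Domains** — hard-edged disks with planted preferences. Hard edges (not
  Gaussian blobs) were chosen deliberately: they make the planted mask an
  unambiguous reference for Dice, equivalent-diameter and overlap recovery,
  at the cost of not exercising soft-boundary behavior. Radii default to
  0.1–0.25 mm (equivalent diameters 0.2–0.5 mm, the V4 domain-size range);
  response amplitudes are drawn per pixel from 1–3 ×10⁻⁴ (0.01–0.03 %).
* **Tuning** — a pixel responds as the **maximum** over the planted
  structures covering it, each structure multiplicative:
  band gate × 180° von-Mises straight-orientation term (κ = 3) ×
  Gaussian degree term × 360° von-Mises curve-orientation term (κ = 3).
  Curvature degree lives on the log coordinate d(r) = 1 + log₂(r) with
  d = 0 for straight; the degree Gaussian has width σ_d. The max-over-
  structures rule (rather than a single per-pixel preference) lets a pixel
  in the overlap of two opposing-orientation subdomains respond to both —
  the quantity the orientation-pair overlap analysis measures. Curvature
  domains additionally carry a response floor to *any* curved grating
  (default 0.15 of peak), encoding their defining preference for curvature
  per se; straight-orientation domains respond to curved gratings only
  through the degree Gaussian evaluated at d(r) (strong for gentle curves,
  negligible for sharp ones), and to scrambled gratings at their mean
  orientation tuning. Color-band pixels respond only to chromatic stimuli.
* **Progressions** — chains of curvature domains of increasing ratio,
  spaced 0.2 mm along the band from a straight domain, with optional
  centroid jitter and optional up/down twin subdomains at a planted IoU.
  Placement is rejection sampling with explicit feasibility corridors;
  infeasible requests raise a `PlacementError` (scenario wrappers retry
  with a shifted stream on the rare infeasible seeds).

### Scenario-specific tuning widths

The degree width σ_d is the one generator parameter that differs between
study scenarios, because the two analyses probe opposite regimes:

* the **similarity** scenario uses σ_d = 1.0 (and the 0.15 curvature floor):
  graded cross-activation between nearby degrees is precisely what produces
  the observed decay of map correlation with degree difference;
* the **progression** scenario uses σ_d = 0.15 with a 0.05 floor: ratios
  4, 5, 7, 10 lie within half an octave of each other, and with broad tuning
  each condition would light neighboring chain domains above threshold,
  merging connected components and biasing centroids — the detectability
  argument, made before running the recovery tests, is that per-ratio
  centroid identification requires neighboring-ratio responses to stay below
  the t ≈ 2.76 threshold (cross-activation ≤ ~0.2 of peak). Progression
  chains are also kept farther apart than their own length (1.3 mm) so the
  nearest-domain rule cannot capture a neighboring chain; a
  many-progression study therefore aggregates 2-chain sessions;
* the **orientation-pair** scenario keeps the default σ_d but lowers the
  curvature floor to 0.05: the planted-IoU recovery measures sharp
  opposing-orientation complementarity, and a floor near threshold would
  leak opposite-orientation pixels into both detected masks, inflating the
  measured overlap.

## Analysis conventions

* Frame labels are 1-based everywhere in interfaces, matching acquisition
  conventions; arrays are 0-based internally.
* The contrast statistic is the paired t (S_i = SD of per-trial differences,
  conditions recorded per block); a Welch unpaired variant exists. The
  printed form of the statistic in the source literature shows a ×N scaling;
  it is implemented as ×√N (the standard t, consistent with the maps being
  called t maps), with `scaling='n'` available for literal display scaling —
  a monotone transform that leaves all p-value thresholding unchanged.
* Map filtering: the "10 pixel diameter" Gaussian is read as a FWHM
  (σ = 10/2.355); the low-frequency estimate is the mean over a circular
  disk (default diameter 120 px from the quoted 100–150 px range) and is
  subtracted. Both filters are NaN-aware and edge-padded. On grids much
  smaller than the 1080×1308 acquisition format the 120 px disk approaches
  the field size and behaves like global-mean removal; the diameters are
  parameters for that reason.
* Domain detection thresholds per-pixel p < 0.01 uncorrected (two-tailed,
  activation sign), replicating the published procedure; a
  Benjamini-Hochberg option is deliberately not applied by default. The
  optional ANOVA gate (p < 0.05 with a vectorized Tukey-Kramer pairwise
  check, `any` or `all` rule) mirrors the extra test applied to curvature
  domains.
* Morphometry: R is the mean semi-axis of the patch's second-moment
  (inertia) ellipse — well-defined for arbitrary shapes — size = πR²,
  equivalent diameter 2R, centroid the unweighted pixel center of mass.
  Patches under 0.2 mm equivalent diameter are excluded as unreliable.
* Overlap percentages are reported as 100·|A∩B|/|A∪B| ("overlapped pixels
  vs. all colored pixels" read as intersection over the union of colored
  sets).
* Similarity uses Pearson correlation over an ROI (default: pixels
  significant vs. blank across the curvature conditions) on *filtered*
  single-condition maps — the displayed maps — with raw-t available; degree
  difference uses ordinal condition ranks.
* Progressions use Euclidean distance in cortical mm (flat-chamber imaging;
  no geodesic correction). The "shifting" flag (Spearman of distance vs.
  ratio > 0.5) is a reporting convenience with a measured null rate of
  ~0.13–0.18, not an inferential claim.
* Timecourse comparisons run the Wilcoxon rank-sum on the ten per-frame
  values within frames 9–18 (clipped with a warning for 16-frame sessions).
  This is the published procedure; successive frames are autocorrelated, so
  the p-values should be read as descriptive. The exact distribution is
  used when the window values are tie-free.

## Numerical choices and degenerate inputs

Zero-variance pixels in t maps become ±inf with p = 0 (p = 1 when the means
also agree); all-zero orientation responses yield magnitude 0 and a flagged
NaN angle; an empty detection result is a valid empty `DomainSet`; two empty
masks have overlap 0 with a warning; a straight domain whose every ratio's
DomainSet is empty raises, single missing ratios are flagged and excluded
pairwise. Simulated sessions default to float32 (a 17-condition 128² session
is ~0.7 GB); float64 is available and used for the 1e-12 closed-form
checks. Nearest-domain ties break toward the lower label id; connected
components default to 8-connectivity (configurable).

## What the simulator does and does not show

The generator reproduces the *statistical structure the analysis assumes*:
amplitudes, timing, trial counts, domain sizes, band layout, graded tuning,
planted progressions, calibrated pixel noise. It does not model eye
movements, breathing/heartbeat artifacts, vessel dynamics, spatially
correlated physiological noise, anesthesia-state drift, or soft domain
boundaries. Passing recovery tests therefore demonstrates that the analysis
correctly inverts its own forward model at realistic SNR — a necessary
condition — not that it is robust to every artifact of real recordings.
Quantities printed in the original study (overlap percentages, 434 µm mean
domain size, specific correlation values) derive from raw imaging stacks
that were never deposited, and are not reproduced here; the package's
validation is parameter recovery on simulation.

## Study sizes

The bundled studies use 128² grids at 25 µm/px (160² for two-chain
progression sessions), 30 trials/condition, 20 repetitions for null
calibration and pinwheel studies, 4 sessions (8 progressions) for spacing
recovery, and 200 geometric layouts for the shifting-flag null — sizes at
which every recovery metric is stable across seeds while a full
`scripts/acceptance.py` run stays around two minutes on one CPU.
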