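"""Synthetic cortical architectures and intrinsic-signal imaging simulation.

The generator plants a ground-truth functional architecture on a pixel grid —
an orientation-preference field with pinwheels, alternating orientation/color
bands, and hard-edged functional domains (straight-orientation domains,
curvature domains with degree and curve-orientation preferences, optional
opposing-orientation subdomain pairs and straight→curved centroid
progressions) — and then simulates block-design reflectance imaging on top of
it.

Conventions
-----------
* Activation *darkens* the image: reflectance(t) = R0·(1 − resp·k(t) + noise),
  with resp ≥ 0 the tuned response fraction and k a gamma-shaped hemodynamic
  kernel with unit peak at 2.5 s.  Downstream difference maps therefore show
  preferred conditions as negative dR/R.
* Response amplitudes are reflectance fractions in [1e-4, 3e-4]
  (0.01–0.03 %), the range typical of cortical intrinsic signals.
* Curvature degree is parameterized by the generating ellipse's a/b ratio;
  tuning operates on the log coordinate d(r) = 1 + log2(r) (d = 0 for
  straight), with a Gaussian of width ``degree_sigma``.
* The frame clock: acquisition starts 0.5 s (= ``n_prestim_frames`` frames at
  4 Hz) before stimulus onset; the kernel is sampled at frame-start times, so
  the first ``n_prestim_frames + 1`` frames carry no evoked signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .stimuli import CURVE_AXIS_DEG, CURVE_ORIENTATION_DEG, StimulusSpec

__all__ = [
    "CortexParams",
    "CorticalModel",
    "PlantedDomain",
    "Progression",
    "NoiseSpec",
    "ImagingSession",
    "PlacementError",
    "make_cortical_model",
    "tuning_response",
    "tuning_response_map",
    "simulate_session",
    "hemodynamic_kernel",
    "pair_separation_for_iou",
]


class PlacementError(RuntimeError):
    """Raised when requested domains cannot be placed inside the bands."""


# --------------------------------------------------------------------------- #
# ground-truth containers
# --------------------------------------------------------------------------- #

@dataclass
class PlantedDomain:
    """One planted functional domain (hard-edged disk)."""

    id: int
    kind: str                      # 'curvature' | 'straight' | 'color' | 'hsf'
    center_px: tuple[float, float]  # (row, col)
    radius_px: float
    ratio: float = 0.0             # preferred a/b ratio (0 = straight)
    phi_deg: float | None = None   # preferred curve orientation (360-periodic)
    theta_deg: float | None = None  # preferred straight orientation (180-per.)
    progression_id: int | None = None

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        r0, c0 = self.center_px
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius_px**2


@dataclass
class Progression:
    """Planted straight→curved centroid progression (ground truth)."""

    straight_centroid_mm: tuple[float, float]
    ratios: tuple[float, ...]
    centroids_mm: list[tuple[float, float]]
    phi_deg: float
    theta_deg: float


@dataclass
class CortexParams:
    """Knobs of the synthetic architecture (defaults emulate V4 imaging)."""

    shape: tuple[int, int] = (128, 128)
    pixel_size_mm: float = 0.025
    # orientation-preference field
    orientation_wavelength_mm: float = 0.7
    # band parcellation (stripes along rows)
    band_period_mm: float = 1.8
    orientation_band_fraction: float = 0.6
    # planted domains
    n_straight_domains: int = 0
    n_curvature_domains: int = 0
    curvature_ratios: tuple[float, ...] = (2.0, 5.0)
    domain_radius_mm: tuple[float, float] = (0.1, 0.2)  # planted radius range
    # orientation-pair subdomains (opposing curve orientations)
    n_orientation_pairs: int = 0
    pair_overlap_iou: float = 0.2
    pair_phi_deg: float | None = None  # fix pair orientation axis (else random)
    # straight→curved progressions
    n_progressions: int = 0
    progression_ratios: tuple[float, ...] = (1.0, 2.0, 4.0, 5.0, 7.0, 10.0)
    progression_spacing_mm: float = 0.2
    progression_jitter_mm: float = 0.0
    progression_paired: bool = False   # add an opposing-orientation twin chain
    progression_phi_deg: float | None = None    # fix curve orientation (else random)
    progression_theta_deg: float | None = None  # fix straight orientation
    # tuning
    degree_sigma: float = 0.8          # Gaussian width in d = 1 + log2(ratio)
    kappa_orientation: float = 3.0     # 180-periodic von Mises concentration
    kappa_curve_orientation: float = 3.0  # 360-periodic concentration
    curvature_response_floor: float = 0.15  # min response of a curvature domain
    #                                        to any curved grating (vs. peak)
    # response amplitude range (reflectance fraction, 0.01-0.03 %)
    amplitude_range: tuple[float, float] = (1e-4, 3e-4)
    min_separation_mm: float = 0.5     # between independently placed domains


@dataclass
class CorticalModel:
    """Ground-truth architecture every simulated session is generated from."""

    shape: tuple[int, int]
    pixel_size_mm: float
    orientation_angle_map: np.ndarray     # degrees in [0, 180)
    orientation_magnitude_map: np.ndarray  # [0, 1]
    band_map: np.ndarray                  # True = orientation band
    sf_pref_map: np.ndarray               # True = high SF preferring
    domains: list[PlantedDomain]
    amplitude_map: np.ndarray
    pinwheel_centers: np.ndarray          # (n, 3): row, col, chirality
    planted_progressions: list[Progression]
    params: CortexParams
    seed: int

    # derived per-pixel preference maps (argmax planted structure)
    curvature_domain_mask: np.ndarray = field(default=None)
    curvature_ratio_pref_map: np.ndarray = field(default=None)
    curvature_orient_pref_map: np.ndarray = field(default=None)

    def domain_mask(self, kind: str) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for d in self.domains:
            if d.kind == kind:
                out |= d.mask(self.shape)
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Acquisition noise model (white pixel noise, slow global drift,
    static vascular pattern)."""

    pixel_noise_sd: float = 1e-4       # reflectance-fraction SD per frame/pixel
    drift_amplitude: float = 1e-5      # global slow drift amplitude
    drift_timescale_s: float = 10.0
    vascular_contrast: float = 0.02    # static multiplicative spatial pattern
    seed: int = 0

    def __post_init__(self):
        for name in ("pixel_noise_sd", "drift_amplitude", "vascular_contrast"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ImagingSession:
    """Block-stored reflectance data: (condition, trial, frame, row, col)."""

    data: np.ndarray
    condition_ids: list[str]
    condition_table: dict[str, StimulusSpec]
    frame_rate_hz: float = 4.0
    n_prestim_frames: int = 2
    stim_duration_s: float = 4.5
    pixel_size_mm: float = 0.025
    seed: int | None = None
    ground_truth: CorticalModel | None = None

    def __post_init__(self):
        expected = self.n_prestim_frames + round(self.stim_duration_s * self.frame_rate_hz)
        if self.data.shape[2] != expected:
            raise ValueError(
                f"frame count {self.data.shape[2]} != n_prestim + stim frames {expected}"
            )
        if len(self.condition_ids) != self.data.shape[0]:
            raise ValueError("condition_ids length must match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[3:]

    def stack(self, condition: str) -> np.ndarray:
        """(trial, frame, row, col) stack for one condition."""
        return self.data[self.condition_ids.index(condition)]


# --------------------------------------------------------------------------- #
# architecture generation
# --------------------------------------------------------------------------- #

def _orientation_field(shape, wavelength_px, rng):
    """Band-pass filtered complex white noise; half-angle gives a 180-periodic
    orientation map with pinwheels at the zeros of the complex field."""
    h, w = shape
    z = rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
    fz = np.fft.fft2(z)
    fr = np.fft.fftfreq(h)[:, None]
    fc = np.fft.fftfreq(w)[None, :]
    k = np.hypot(fr, fc)
    k0 = 1.0 / wavelength_px
    band = np.exp(-((k - k0) ** 2) / (2 * (0.35 * k0) ** 2))
    zf = np.fft.ifft2(fz * band)
    angle = (np.rad2deg(np.angle(zf)) / 2.0) % 180.0
    mag = np.abs(zf)
    mag = mag / mag.max() if mag.max() > 0 else mag
    return angle, mag


def _winding_pinwheels(angle_deg: np.ndarray, periodic: bool = False) -> np.ndarray:
    """Plaquette winding of the doubled angle; shared with featuremaps."""
    from .featuremaps import detect_pinwheels

    return detect_pinwheels(angle_deg, smooth_sigma=0.0, periodic=periodic)


def pair_separation_for_iou(radius: float, target_iou: float) -> float:
    """Center separation of two equal disks whose masks intersect at the
    requested intersection-over-union (solved numerically)."""
    if not 0 < target_iou < 1:
        raise ValueError("target_iou must be in (0, 1)")

    def iou(d):
        if d >= 2 * radius:
            return 0.0
        lens = 2 * radius**2 * math.acos(d / (2 * radius)) - (d / 2) * math.sqrt(
            max(4 * radius**2 - d**2, 0.0)
        )
        return lens / (2 * math.pi * radius**2 - lens)

    lo, hi = 0.0, 2 * radius
    for _ in range(80):
        mid = (lo + hi) / 2
        if iou(mid) > target_iou:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _disk_in_band(band_map, center, radius_px) -> bool:
    h, w = band_map.shape
    r0, c0 = center
    if not (radius_px <= r0 < h - radius_px and radius_px <= c0 < w - radius_px):
        return False
    rr, cc = np.ogrid[:h, :w]
    disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    return bool(band_map[disk].all())


def _place_center(rng, shape, band_map, radius_px, taken, min_sep_px, margin_px,
                  max_tries=2000):
    """Random center with the whole disk inside the orientation band and at
    least ``min_sep_px`` from previously taken centers."""
    h, w = shape
    for _ in range(max_tries):
        r = rng.uniform(margin_px, h - margin_px)
        c = rng.uniform(margin_px, w - margin_px)
        if not _disk_in_band(band_map, (r, c), radius_px):
            continue
        if all((r - tr) ** 2 + (c - tc) ** 2 >= min_sep_px**2 for tr, tc in taken):
            return r, c
    raise PlacementError(
        f"could not place a domain of radius {radius_px:.1f} px inside the "
        "orientation band; reduce domain size or count"
    )


def make_cortical_model(params: CortexParams | None = None, seed: int = 0) -> CorticalModel:
    """Generate a ground-truth cortical architecture; deterministic given seed."""
    params = params or CortexParams()
    rng = np.random.default_rng(seed)
    shape = tuple(params.shape)
    px = params.pixel_size_mm
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError("grid must be at least 64x64")

    angle, mag = _orientation_field(shape, params.orientation_wavelength_mm / px, rng)
    pin = _winding_pinwheels(angle)

    # band parcellation: stripes along rows, thresholded to the requested
    # orientation-band area fraction
    rows = np.arange(h)[:, None] * px
    phase0 = rng.uniform(0, 2 * np.pi)
    stripe = np.sin(2 * np.pi * rows / params.band_period_mm + phase0)
    stripe = np.broadcast_to(stripe, shape)
    thresh = np.quantile(stripe, 1.0 - params.orientation_band_fraction)
    band_map = stripe >= thresh

    sf_pref = rng.random(shape) < 0.5  # unstructured high/low SF preference

    domains: list[PlantedDomain] = []
    progressions: list[Progression] = []
    taken: list[tuple[float, float]] = []
    next_id = 1
    min_sep_px = params.min_separation_mm / px

    def add(kind, center, radius_px, **kw):
        nonlocal next_id
        d = PlantedDomain(id=next_id, kind=kind, center_px=center,
                          radius_px=radius_px, **kw)
        domains.append(d)
        next_id += 1
        return d

    def rand_radius():
        lo, hi = params.domain_radius_mm
        return rng.uniform(lo, hi) / px

    def far_enough(points):
        return all(
            (r - tr) ** 2 + (c - tc) ** 2 >= min_sep_px**2
            for (r, c) in points for (tr, tc) in taken
        )

    # straight→curved centroid progressions (placed first: most constrained)
    spacing_px = params.progression_spacing_mm / px
    n_steps = len(params.progression_ratios)
    for i in range(params.n_progressions):
        rad = rand_radius()
        pad = rad + 4.0 * params.progression_jitter_mm / px
        if params.progression_paired:
            pad += pair_separation_for_iou(rad, params.pair_overlap_iou) / 2
        # chains run along the band stripes (constant row); rows with a clear
        # corridor of half-height ``pad`` inside the band are precomputed
        row_ok = np.array([
            band_map[max(int(r - pad), 0):int(r + pad) + 1, :].all()
            and pad <= r < h - pad
            for r in range(h)
        ])
        ok_rows = np.nonzero(row_ok)[0]
        placed = False
        if ok_rows.size:
            length = spacing_px * n_steps
            for _ in range(4000):
                sgn = rng.choice([1.0, -1.0])
                dvec = np.array([0.0, sgn])
                row = float(rng.choice(ok_rows))
                col = rng.uniform(pad + 2, w - pad - 2 - length)
                start = (row, col if sgn > 0 else w - col)
                chain = [np.array(start) + dvec * spacing_px * (k + 1)
                         for k in range(n_steps)]
                if far_enough([start] + [tuple(c) for c in chain]):
                    placed = True
                    break
        if not placed:
            raise PlacementError("could not fit a progression inside the band")
        taken.append(start)
        taken.extend(tuple(c) for c in chain)
        theta = (params.progression_theta_deg if params.progression_theta_deg
                 is not None else float(rng.choice([0.0, 45.0, 90.0, 135.0])))
        phi = (params.progression_phi_deg if params.progression_phi_deg
               is not None else float(rng.choice([0.0, 90.0, 180.0, 270.0])))
        add("straight", start, rad, theta_deg=theta, progression_id=i)
        cents = []
        pair_off = None
        if params.progression_paired:
            sep = pair_separation_for_iou(rad, params.pair_overlap_iou)
            perp = np.array([-dvec[1], dvec[0]])
            pair_off = perp * sep / 2
        for k, ratio in enumerate(params.progression_ratios):
            pos = np.array(start) + dvec * spacing_px * (k + 1)
            if params.progression_jitter_mm > 0:
                pos = pos + rng.normal(0, params.progression_jitter_mm / px, 2)
            if pair_off is not None:
                add("curvature", tuple(pos + pair_off), rad, ratio=float(ratio),
                    phi_deg=(phi + 180.0) % 360.0, progression_id=i)
                add("curvature", tuple(pos - pair_off), rad, ratio=float(ratio),
                    phi_deg=phi, progression_id=i)
                cents.append(((pos - pair_off)[0] * px, (pos - pair_off)[1] * px))
            else:
                add("curvature", tuple(pos), rad, ratio=float(ratio),
                    phi_deg=phi, progression_id=i)
                cents.append((pos[0] * px, pos[1] * px))
        progressions.append(Progression(
            straight_centroid_mm=(start[0] * px, start[1] * px),
            ratios=tuple(params.progression_ratios),
            centroids_mm=cents, phi_deg=phi, theta_deg=theta))

    # opposing-orientation subdomain pairs at a planted IoU
    for i in range(params.n_orientation_pairs):
        rad = rand_radius()
        sep = pair_separation_for_iou(rad, params.pair_overlap_iou)
        center = _place_center(rng, shape, band_map, rad + sep, taken,
                               min_sep_px, rad + sep + 2)
        taken.append(center)
        ang = rng.uniform(0, 2 * np.pi)
        dr, dc = (sep / 2) * math.sin(ang), (sep / 2) * math.cos(ang)
        phi = (params.pair_phi_deg if params.pair_phi_deg is not None
               else float(rng.choice([0.0, 90.0])))
        ratio = float(rng.choice(params.curvature_ratios))
        r0, c0 = center
        add("curvature", (r0 - dr, c0 - dc), rad, ratio=ratio, phi_deg=phi)
        add("curvature", (r0 + dr, c0 + dc), rad, ratio=ratio, phi_deg=phi + 180.0)

    # straight-orientation domains
    for i in range(params.n_straight_domains):
        rad = rand_radius()
        center = _place_center(rng, shape, band_map, rad, taken, min_sep_px, rad + 2)
        taken.append(center)
        add("straight", center, rad, theta_deg=float(rng.choice([0, 45, 90, 135])))

    # standalone curvature domains
    for i in range(params.n_curvature_domains):
        rad = rand_radius()
        center = _place_center(rng, shape, band_map, rad, taken, min_sep_px, rad + 2)
        taken.append(center)
        add("curvature", center, rad,
            ratio=float(rng.choice(params.curvature_ratios)),
            phi_deg=float(rng.choice([0.0, 90.0, 180.0, 270.0])))

    lo, hi = params.amplitude_range
    amplitude_map = rng.uniform(lo, hi, size=shape)

    model = CorticalModel(
        shape=shape, pixel_size_mm=px,
        orientation_angle_map=angle, orientation_magnitude_map=mag,
        band_map=band_map, sf_pref_map=sf_pref,
        domains=domains, amplitude_map=amplitude_map,
        pinwheel_centers=pin, planted_progressions=progressions,
        params=params, seed=seed,
    )
    _derive_pref_maps(model)
    return model


def _derive_pref_maps(model: CorticalModel) -> None:
    shape = model.shape
    cmask = np.zeros(shape, dtype=bool)
    ratio_pref = np.zeros(shape)
    orient_pref = np.full(shape, np.nan)
    for d in model.domains:
        if d.kind != "curvature":
            continue
        m = d.mask(shape)
        new = m & ~cmask
        cmask |= m
        ratio_pref[new] = d.ratio
        orient_pref[new] = d.phi_deg if d.phi_deg is not None else np.nan
    model.curvature_domain_mask = cmask
    model.curvature_ratio_pref_map = ratio_pref
    model.curvature_orient_pref_map = orient_pref


# --------------------------------------------------------------------------- #
# tuning
# --------------------------------------------------------------------------- #

def _degree_coord(ratio: float) -> float:
    """Log curvature-degree coordinate: 0 for straight, 1 + log2(ratio) else."""
    if ratio <= 0:
        return 0.0
    return 1.0 + math.log2(max(ratio, 1.0))


def _vm180(delta_deg, kappa):
    return np.exp(kappa * (np.cos(2 * np.deg2rad(delta_deg)) - 1.0))


def _vm360(delta_deg, kappa):
    return np.exp(kappa * (np.cos(np.deg2rad(delta_deg)) - 1.0))


def _domain_tuning(d: PlantedDomain, spec: StimulusSpec, p: CortexParams) -> float:
    """Tuning factor in [0, 1] of one planted domain for one stimulus."""
    if spec.kind == "blank":
        return 0.0
    if d.kind == "color":
        return 1.0 if spec.chromatic else 0.0
    if spec.chromatic:
        return 0.0
    if d.kind == "hsf":
        return 1.0 if spec.sf_cpd >= 2.0 else 0.35

    curved = spec.kind in ("curved_grating", "curved_line")
    scrambled = spec.kind == "scrambled_grating"
    sigma = p.degree_sigma
    if d.kind == "straight":
        # degree term vs the domain's straight preference (d = 0)
        d_stim = 0.0 if (not curved or scrambled) else _degree_coord(spec.curvature_ratio)
        deg = math.exp(-(d_stim**2) / (2 * sigma**2))
        if curved:
            theta_stim = CURVE_AXIS_DEG[spec.curve_orientation]
            ori = float(_vm180(theta_stim - d.theta_deg, p.kappa_orientation))
        elif scrambled:
            # all orientations present: mean tuning over the four cardinals
            ori = float(np.mean(_vm180(np.array([0, 45, 90, 135]) - d.theta_deg,
                                       p.kappa_orientation)))
        else:
            ori = float(_vm180(float(spec.curve_orientation) - d.theta_deg,
                               p.kappa_orientation))
        return deg * ori
    if d.kind == "curvature":
        d_pref = _degree_coord(d.ratio)
        # scrambling destroys the curvature structure
        d_stim = _degree_coord(spec.curvature_ratio) if curved else 0.0
        deg = math.exp(-((d_stim - d_pref) ** 2) / (2 * sigma**2))
        if curved and d.phi_deg is not None:
            phi_stim = CURVE_ORIENTATION_DEG[spec.curve_orientation]
            deg *= float(_vm360(phi_stim - d.phi_deg, p.kappa_curve_orientation))
        if curved:
            # curvature domains prefer curvature per se: a weak response to
            # any curved stimulus, regardless of its degree and orientation
            deg = max(deg, p.curvature_response_floor)
        return deg
    raise ValueError(f"unknown domain kind {d.kind!r}")


def tuning_response_map(model: CorticalModel, spec: StimulusSpec) -> np.ndarray:
    """Per-pixel peak response fraction (>= 0) to one stimulus.

    Each pixel responds as the *maximum* over the planted structures covering
    it (a pixel inside the overlap of two opposing-orientation subdomains
    responds to both orientations), scaled by the pixel's amplitude.
    """
    tuning = np.zeros(model.shape)
    if spec.kind != "blank":
        if spec.chromatic:
            tuning[~model.band_map] = 1.0  # color band responds to chromatic
        for d in model.domains:
            t = _domain_tuning(d, spec, model.params)
            if t <= 0:
                continue
            m = d.mask(model.shape)
            np.maximum(tuning, np.where(m, t, 0.0), out=tuning)
    return model.amplitude_map * tuning


def tuning_response(model: CorticalModel, pixel: tuple[int, int],
                    spec: StimulusSpec) -> float:
    """Peak response fraction of one pixel to one stimulus."""
    r, c = pixel
    if not (0 <= r < model.shape[0] and 0 <= c < model.shape[1]):
        raise IndexError(f"pixel {pixel} outside grid {model.shape}")
    return float(tuning_response_map(model, spec)[r, c])


# --------------------------------------------------------------------------- #
# imaging simulation
# --------------------------------------------------------------------------- #

def hemodynamic_kernel(t_s: np.ndarray, peak_s: float = 2.5,
                       shape: float = 4.0) -> np.ndarray:
    """Gamma-shaped intrinsic-signal kernel with unit peak at ``peak_s``."""
    t = np.asarray(t_s, dtype=float)
    k = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / peak_s
    k[pos] = x ** (shape - 1.0) * np.exp((shape - 1.0) * (1.0 - x))
    return k


def frame_onset_times(n_frames: int, frame_rate_hz: float = 4.0,
                      n_prestim_frames: int = 2) -> np.ndarray:
    """Frame-start times relative to stimulus onset (s)."""
    return np.arange(n_frames) / frame_rate_hz - n_prestim_frames / frame_rate_hz


def simulate_session(
    model: CorticalModel,
    condition_table: dict[str, StimulusSpec],
    n_trials: int = 30,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    stim_duration_s: float = 4.5,
    frame_rate_hz: float = 4.0,
    n_prestim_frames: int = 2,
    baseline: float = 10000.0,
    kernel_peak_s: float = 2.5,
    dtype=np.float32,
) -> ImagingSession:
    """Forward-simulate one block-design imaging session.

    reflectance = baseline·(1 + vascular)·(1 − resp·k(t) + drift + ε), with
    ε white per pixel/frame and drift a slow global sinusoid per trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng([seed, noise.seed])
    n_frames = n_prestim_frames + round(stim_duration_s * frame_rate_hz)
    h, w = model.shape
    cond_ids = list(condition_table)
    t_rel = frame_onset_times(n_frames, frame_rate_hz, n_prestim_frames)
    kern = hemodynamic_kernel(t_rel, peak_s=kernel_peak_s)

    if noise.vascular_contrast > 0:
        from scipy.ndimage import gaussian_filter

        vasc = gaussian_filter(rng.standard_normal((h, w)), 3.0)
        vasc *= noise.vascular_contrast / max(np.abs(vasc).max(), 1e-12)
    else:
        vasc = np.zeros((h, w))
    dtype = np.dtype(dtype)
    base = (baseline * (1.0 + vasc)).astype(dtype)

    data = np.empty((len(cond_ids), n_trials, n_frames, h, w), dtype=dtype)
    t_abs = np.arange(n_frames) / frame_rate_hz
    for ci, cid in enumerate(cond_ids):
        resp = tuning_response_map(model, condition_table[cid])
        evoked = (1.0 - resp[None, :, :] * kern[:, None, None]).astype(dtype)
        for tr in range(n_trials):
            frame = evoked.copy()
            if noise.drift_amplitude > 0:
                phase = rng.uniform(0, 2 * np.pi)
                amp = noise.drift_amplitude * rng.uniform(0.5, 1.5)
                drift = amp * np.sin(2 * np.pi * t_abs / noise.drift_timescale_s + phase)
                frame += drift.astype(dtype)[:, None, None]
            if noise.pixel_noise_sd > 0:
                eps = rng.standard_normal((n_frames, h, w), dtype=np.float32)
                frame += eps.astype(dtype) * dtype.type(noise.pixel_noise_sd)
            data[ci, tr] = base[None] * frame

    return ImagingSession(
        data=data, condition_ids=cond_ids, condition_table=dict(condition_table),
        frame_rate_hz=frame_rate_hz, n_prestim_frames=n_prestim_frames,
        stim_duration_s=stim_duration_s, pixel_size_mm=model.pixel_size_mm,
        seed=seed, ground_truth=model,
    )
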