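"""Rendering of curvature-grating stimuli and controls.

Curved gratings are built from an ellipse X²/a² + Y²/b² = 1: one half-ellipse
arc is expressed as a vertical displacement field

    Δ(x) = a · (1 − sqrt(1 − x²/b²)),   |x| ≤ b,

with b the half-width of the stimulus aperture and a = ratio·b, where
ratio = a/b is the curvature index (0 ⇒ straight).  A drifting grating is a
sinusoid of the phase coordinate u = y + Δ(x) (for an upward-pointing apex);
the profile along the central axis x = 0 is therefore a plain sinusoid of the
nominal spatial frequency, independent of curvature, while the local spatial
frequency on the flanks grows with the curvature index.

All luminance images are normalized to [0, 1] with mean luminance 0.5 for
gratings.  Angles are in degrees; spatial frequency in cycles/degree.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSpec",
    "StimulusFrame",
    "curvature_index",
    "render_frame",
    "render_curved_grating",
    "render_straight_grating",
    "render_flashed_line",
    "scramble_stimulus",
    "scramble_permutation",
    "apply_block_permutation",
    "GRATING_KINDS",
    "CURVE_ORIENTATIONS",
]

GRATING_KINDS = (
    "curved_grating",
    "straight_grating",
    "curved_line",
    "straight_line",
    "scrambled_grating",
    "blank",
)

#: apex direction of the curve -> (use y/x as the bent axis, sign)
CURVE_ORIENTATIONS = ("up", "down", "left", "right")

#: curve orientation as an angle (degrees, 360-periodic, apex direction)
CURVE_ORIENTATION_DEG = {"up": 90.0, "right": 0.0, "down": 270.0, "left": 180.0}

#: orientation (180-periodic) of the contour at the curve's vertex
CURVE_AXIS_DEG = {"up": 0.0, "down": 0.0, "left": 90.0, "right": 90.0}


def curvature_index(a: float, b: float) -> float:
    """Curvature index of the generating ellipse: long over short axis, a/b.

    Raises ``ValueError`` for non-positive axes.
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"ellipse axes must be positive, got a={a}, b={b}")
    return a / b


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of one stimulus condition."""

    kind: str
    curvature_ratio: float = 0.0
    curve_orientation: str | float = "up"
    sf_cpd: float = 1.0
    size_deg: float = 4.0
    drift_speed_deg_s: float = 2.0
    phase: float = 0.0
    n_scramble_subunits: int = 64
    seed: int = 0
    chromatic: bool = False

    def __post_init__(self) -> None:
        if self.kind not in GRATING_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.size_deg <= 0:
            raise ValueError("size_deg must be > 0")
        if self.kind != "blank" and self.sf_cpd <= 0:
            raise ValueError("sf_cpd must be > 0")
        curved = self.kind in ("curved_grating", "curved_line", "scrambled_grating")
        if curved and self.curvature_ratio <= 0:
            raise ValueError(f"{self.kind} requires curvature_ratio > 0")
        if not curved and self.curvature_ratio != 0:
            raise ValueError(f"{self.kind} requires curvature_ratio == 0")
        if curved and self.curve_orientation not in CURVE_ORIENTATIONS:
            raise ValueError(
                f"curve_orientation must be one of {CURVE_ORIENTATIONS}"
            )
        root = np.sqrt(self.n_scramble_subunits)
        if int(root) ** 2 != self.n_scramble_subunits:
            raise ValueError("n_scramble_subunits must be a perfect square")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(**d)


@dataclass
class StimulusFrame:
    """One rendered luminance image, values in [0, 1]."""

    luminance: np.ndarray
    pixel_pitch_deg: float
    spec: StimulusSpec
    frame_index: int = 0


def _grid(size_deg: float, pixel_pitch_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Centered pixel coordinates (x right, y up) in degrees."""
    n = int(round(size_deg / pixel_pitch_deg))
    c = (n - 1) / 2.0
    cols = (np.arange(n) - c) * pixel_pitch_deg
    rows = (c - np.arange(n)) * pixel_pitch_deg
    x, y = np.meshgrid(cols, rows)
    return x, y


def _displacement(x: np.ndarray, ratio: float, half_width: float) -> np.ndarray:
    """Half-ellipse displacement Δ(x) = a(1 − sqrt(1 − x²/b²)), a = ratio·b."""
    b = half_width
    a = ratio * b
    inner = np.clip(1.0 - (x / b) ** 2, 0.0, None)
    return a * (1.0 - np.sqrt(inner))


def _phase_coordinate(
    x: np.ndarray, y: np.ndarray, ratio: float, curve_orientation: str, size_deg: float
) -> np.ndarray:
    """u(x, y) such that sin(2π·sf·u) draws curves with the requested apex."""
    b = size_deg / 2.0
    if curve_orientation == "up":
        return y + _displacement(x, ratio, b)
    if curve_orientation == "down":
        return -y + _displacement(x, ratio, b)
    if curve_orientation == "right":
        return x + _displacement(y, ratio, b)
    if curve_orientation == "left":
        return -x + _displacement(y, ratio, b)
    raise ValueError(f"unknown curve orientation {curve_orientation!r}")


def curved_grating_image(
    ratio: float,
    curve_orientation: str,
    sf_cpd: float,
    size_deg: float = 4.0,
    pixel_pitch_deg: float = 0.01,
    t: float = 0.0,
    drift_speed_deg_s: float = 2.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Luminance image of a (possibly degenerate, ratio=0) curved grating."""
    x, y = _grid(size_deg, pixel_pitch_deg)
    u = _phase_coordinate(x, y, ratio, curve_orientation, size_deg)
    return 0.5 + 0.5 * np.sin(2 * np.pi * sf_cpd * (u - drift_speed_deg_s * t) + phase)


def straight_grating_image(
    orientation_deg: float,
    sf_cpd: float,
    size_deg: float = 4.0,
    pixel_pitch_deg: float = 0.01,
    t: float = 0.0,
    drift_speed_deg_s: float = 2.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Drifting sinusoidal grating at the given contour orientation."""
    theta = np.deg2rad(orientation_deg % 180.0)
    x, y = _grid(size_deg, pixel_pitch_deg)
    u = y * np.cos(theta) - x * np.sin(theta)
    return 0.5 + 0.5 * np.sin(2 * np.pi * sf_cpd * (u - drift_speed_deg_s * t) + phase)


def render_curved_grating(spec: StimulusSpec, t: float = 0.0,
                          pixel_pitch_deg: float = 0.01,
                          frame_index: int = 0) -> StimulusFrame:
    if spec.kind != "curved_grating":
        raise ValueError("spec.kind must be 'curved_grating'")
    lum = curved_grating_image(
        spec.curvature_ratio, spec.curve_orientation, spec.sf_cpd, spec.size_deg,
        pixel_pitch_deg, t, spec.drift_speed_deg_s, spec.phase,
    )
    return StimulusFrame(lum, pixel_pitch_deg, spec, frame_index)


def render_straight_grating(spec: StimulusSpec, t: float = 0.0,
                            pixel_pitch_deg: float = 0.01,
                            frame_index: int = 0) -> StimulusFrame:
    if spec.kind != "straight_grating":
        raise ValueError("spec.kind must be 'straight_grating'")
    lum = straight_grating_image(
        float(spec.curve_orientation), spec.sf_cpd, spec.size_deg,
        pixel_pitch_deg, t, spec.drift_speed_deg_s, spec.phase,
    )
    return StimulusFrame(lum, pixel_pitch_deg, spec, frame_index)


def render_flashed_line(spec: StimulusSpec, on: bool = True,
                        pixel_pitch_deg: float = 0.01,
                        line_width_deg: float = 0.05,
                        frame_index: int = 0) -> StimulusFrame:
    """Single bright curved/straight line on black, vertex fixed at center.

    ``on=False`` renders the interleaved black screen.
    """
    if spec.kind not in ("curved_line", "straight_line"):
        raise ValueError("spec.kind must be 'curved_line' or 'straight_line'")
    x, y = _grid(spec.size_deg, pixel_pitch_deg)
    if not on:
        return StimulusFrame(np.zeros_like(x), pixel_pitch_deg, spec, frame_index)
    if spec.kind == "curved_line":
        u = _phase_coordinate(x, y, spec.curvature_ratio, spec.curve_orientation,
                              spec.size_deg)
    else:
        theta = np.deg2rad(float(spec.curve_orientation) % 180.0)
        u = y * np.cos(theta) - x * np.sin(theta)
    lum = (np.abs(u) <= line_width_deg / 2.0).astype(float)
    return StimulusFrame(lum, pixel_pitch_deg, spec, frame_index)


def render_frame(spec: StimulusSpec, t: float = 0.0,
                 pixel_pitch_deg: float = 0.01, on: bool = True) -> StimulusFrame:
    """Render any stimulus kind at time ``t`` (seconds into the drift)."""
    if spec.kind == "curved_grating":
        return render_curved_grating(spec, t, pixel_pitch_deg)
    if spec.kind == "straight_grating":
        return render_straight_grating(spec, t, pixel_pitch_deg)
    if spec.kind in ("curved_line", "straight_line"):
        return render_flashed_line(spec, on, pixel_pitch_deg)
    if spec.kind == "scrambled_grating":
        base = dataclasses.replace(spec, kind="curved_grating")
        frame = render_curved_grating(base, t, pixel_pitch_deg)
        return scramble_stimulus(frame, spec.n_scramble_subunits, spec.seed)
    if spec.kind == "blank":
        n = int(round(spec.size_deg / pixel_pitch_deg))
        return StimulusFrame(np.full((n, n), 0.5), pixel_pitch_deg, spec)
    raise ValueError(f"unknown stimulus kind {spec.kind!r}")


# -- block scrambling ---------------------------------------------------------

def scramble_permutation(n_subunits: int, seed: int) -> np.ndarray:
    """Random permutation of the √n×√n block grid (flat block indices)."""
    g = int(round(np.sqrt(n_subunits)))
    if g * g != n_subunits:
        raise ValueError("n_subunits must be a perfect square")
    rng = np.random.default_rng(seed)
    return rng.permutation(n_subunits)


def apply_block_permutation(img: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Rearrange the √n×√n block grid of ``img`` by ``perm``.

    The image is center-cropped to the largest block-divisible size so the
    permutation is exact (pixel multiset preserved bit-for-bit).
    """
    n = perm.size
    g = int(round(np.sqrt(n)))
    if g * g != n:
        raise ValueError("permutation length must be a perfect square")
    h, w = img.shape
    ch, cw = (h // g) * g, (w // g) * g
    r0, c0 = (h - ch) // 2, (w - cw) // 2
    crop = img[r0:r0 + ch, c0:c0 + cw]
    bh, bw = ch // g, cw // g
    blocks = crop.reshape(g, bh, g, bw).transpose(0, 2, 1, 3).reshape(n, bh, bw)
    shuffled = blocks[perm]
    out = shuffled.reshape(g, g, bh, bw).transpose(0, 2, 1, 3).reshape(ch, cw)
    return out


def scramble_stimulus(frame: StimulusFrame, n_subunits: int = 64,
                      seed: int = 0) -> StimulusFrame:
    """Divide the image into ``n_subunits`` blocks and shuffle their positions."""
    perm = scramble_permutation(n_subunits, seed)
    out = apply_block_permutation(frame.luminance, perm)
    return StimulusFrame(out, frame.pixel_pitch_deg, frame.spec, frame.frame_index)
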