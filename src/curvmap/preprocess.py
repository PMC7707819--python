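"""Per-trial response maps and condition-contrast statistic maps.

The basic response unit is the fractional reflectance change
dR/R = (F_x − F_0)/F_0 with F_0 the mean of the pre-stimulus frames.  A
trial's scalar response per pixel is (R̄_{8–16} − R̄_{1–3})/R̄_{1–3}, i.e. the
mean reflectance over frames 8–16 relative to frames 1–3 (frame labels are
1-based throughout, matching acquisition conventions at 4 Hz with 2
pre-stimulus frames).

Condition contrasts are per-pixel t statistics
t_i = (R̄_i1 − R̄_i2)·√N / S_i with S_i the standard deviation of the
per-trial differences (trials are paired within blocks); a Welch unpaired
variant is available.  A ``scaling='n'`` option reproduces the literal ×N
display scaling (a monotone transform; p-values are always from the √N
statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

__all__ = [
    "ResponseMap",
    "SingleConditionResult",
    "BASELINE_FRAMES",
    "RESPONSE_FRAMES",
    "frame_drr",
    "trial_response",
    "difference_statistic_map",
    "filter_map",
    "single_condition_map",
]

#: 1-based inclusive frame windows used for the per-trial scalar response
BASELINE_FRAMES = (1, 3)
RESPONSE_FRAMES = (8, 16)


@dataclass
class ResponseMap:
    """A 2-D per-pixel map with its defining contrast and ROI."""

    values: np.ndarray
    kind: str  # 'drr_diff' | 't_value' | 'p_value' | 'single_condition'
    contrast: tuple | None = None
    roi: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


def frame_drr(stack: np.ndarray, n_baseline_frames: int = 2) -> np.ndarray:
    """Per-frame dR/R relative to the mean of the first frames.

    ``stack`` has frames on axis -3 (``(frames, rows, cols)`` or any leading
    trial/condition axes before that).  Raises on non-positive baselines,
    naming the offending pixel.
    """
    stack = np.asarray(stack)
    if stack.ndim < 3:
        raise ValueError("stack must be at least (frames, rows, cols)")
    if stack.shape[-3] < n_baseline_frames:
        raise ValueError(
            f"stack has {stack.shape[-3]} frames < {n_baseline_frames} baseline frames"
        )
    f0 = stack[..., :n_baseline_frames, :, :].mean(axis=-3, keepdims=True)
    bad = f0 <= 0
    if bad.any():
        idx = np.unravel_index(np.argmax(bad), bad.shape)
        raise ZeroDivisionError(
            f"non-positive baseline at pixel (row={idx[-2]}, col={idx[-1]})"
        )
    return (stack - f0) / f0


def trial_response(stack: np.ndarray,
                   baseline_frames: tuple[int, int] = BASELINE_FRAMES,
                   response_frames: tuple[int, int] = RESPONSE_FRAMES) -> np.ndarray:
    """Scalar per-pixel response: (R̄_resp − R̄_base)/R̄_base per trial.

    Frame windows are 1-based inclusive.  Works on a single-trial
    ``(frames, rows, cols)`` stack or any stack with frames on axis -3
    (e.g. ``(trials, frames, rows, cols)`` → one map per trial).
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim < 3:
        raise ValueError("stack must be at least (frames, rows, cols)")
    n = stack.shape[-3]
    if n < response_frames[1]:
        raise ValueError(
            f"stack has {n} frames; frames {response_frames[0]}–{response_frames[1]} "
            "are required (no silent truncation)"
        )
    b0, b1 = baseline_frames
    r0, r1 = response_frames
    base = stack[..., b0 - 1:b1, :, :].mean(axis=-3)
    if (base <= 0).any():
        idx = np.unravel_index(np.argmax(base <= 0), base.shape)
        raise ZeroDivisionError(
            f"non-positive baseline at pixel (row={idx[-2]}, col={idx[-1]})"
        )
    resp = stack[..., r0 - 1:r1, :, :].mean(axis=-3)
    return (resp - base) / base


def difference_statistic_map(
    group_a: np.ndarray,
    group_b: np.ndarray,
    paired: bool = True,
    scaling: str = "sqrt_n",
    contrast: tuple | None = None,
) -> tuple[ResponseMap, ResponseMap]:
    """Pixel-wise two-tailed t statistic between two groups of trial maps.

    ``group_a``/``group_b`` are ``(n_trials, rows, cols)``.  Paired (default):
    t = mean(d)·√N / sd(d), d the per-trial difference.  Zero-variance pixels
    get t = ±inf with p = 0 (or t = 0, p = 1 when the means agree too).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must be (n_trials, rows, cols) with equal maps")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 trials")
    if scaling not in ("sqrt_n", "n"):
        raise ValueError("scaling must be 'sqrt_n' or 'n'")

    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired groups must have equal trial counts")
        n = a.shape[0]
        d = a - b
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        df = n - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean * np.sqrt(n) / sd
        zero = sd == 0
        with np.errstate(invalid="ignore"):
            t[zero] = np.where(mean[zero] == 0, 0.0, np.sign(mean[zero]) * np.inf)
        scale = np.sqrt(n) if scaling == "sqrt_n" else float(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_disp = mean * scale / np.where(sd == 0, np.nan, sd)
        t_disp[zero] = t[zero]
    else:
        na, nb = a.shape[0], b.shape[0]
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        se2 = va / na + vb / nb
        mean = a.mean(axis=0) - b.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(se2)
            df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
        zero = se2 == 0
        t[zero] = np.where(mean[zero] == 0, 0.0, np.sign(mean[zero]) * np.inf)
        df = np.where(zero, na + nb - 2, df)
        t_disp = t

    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(t == 0, 1.0, p)
    prov = {"paired": paired, "n": (a.shape[0], b.shape[0]), "scaling": scaling}
    return (
        ResponseMap(t_disp, "t_value", contrast=contrast, provenance=prov),
        ResponseMap(p, "p_value", contrast=contrast, provenance=prov),
    )


def _nan_aware_convolve(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Edge-padded FFT convolution ignoring NaNs (renormalized weights)."""
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    pad_r = kernel.shape[0] // 2
    pad_c = kernel.shape[1] // 2
    pads = ((pad_r, kernel.shape[0] - 1 - pad_r), (pad_c, kernel.shape[1] - 1 - pad_c))
    fp = np.pad(filled, pads, mode="edge")
    mp = np.pad(finite.astype(float), pads, mode="edge")
    num = signal.fftconvolve(fp, kernel, mode="valid")
    den = signal.fftconvolve(mp, kernel, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~finite] = np.nan
    return out


def filter_map(
    values: np.ndarray | ResponseMap,
    smooth_diameter_px: float = 10.0,
    lowfreq_diameter_px: float = 120.0,
) -> np.ndarray | ResponseMap:
    """High-pass map filtering: Gaussian smoothing minus a circular-mean
    low-frequency estimate.

    The Gaussian "diameter" is read as a FWHM (σ = diameter/2.355); the
    low-frequency component is the mean over a circular disk of the given
    diameter and is subtracted, removing DC and slow gradients.  NaNs (pixels
    outside the ROI) are ignored by both filters and preserved in the output.
    """
    if smooth_diameter_px < 1 or lowfreq_diameter_px < 1:
        raise ValueError("filter diameters must be >= 1 px")
    if lowfreq_diameter_px <= smooth_diameter_px:
        raise ValueError("low-frequency diameter must exceed the smoothing diameter")
    is_map = isinstance(values, ResponseMap)
    v = np.asarray(values.values if is_map else values, dtype=np.float64)

    sigma = smooth_diameter_px / 2.355
    finite = np.isfinite(v)
    if finite.all():
        smooth = ndimage.gaussian_filter(v, sigma, mode="nearest")
    else:
        filled = np.where(finite, v, 0.0)
        num = ndimage.gaussian_filter(filled, sigma, mode="nearest")
        den = ndimage.gaussian_filter(finite.astype(float), sigma, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            smooth = num / den
        smooth[~finite] = np.nan

    rad = lowfreq_diameter_px / 2.0
    n = int(np.ceil(rad)) * 2 + 1
    yy, xx = np.mgrid[:n, :n] - n // 2
    disk = ((yy**2 + xx**2) <= rad**2).astype(float)
    disk /= disk.sum()
    low = _nan_aware_convolve(v, disk)

    out = smooth - low
    if is_map:
        return ResponseMap(out, values.kind, contrast=values.contrast,
                           roi=values.roi,
                           provenance={**values.provenance, "filtered": True})
    return out


@dataclass
class SingleConditionResult:
    """t/p maps of one condition against the average of straight gratings."""

    t: ResponseMap          # unfiltered t map (p is derived from this one)
    p: ResponseMap
    filtered: ResponseMap   # band-pass filtered t map, as displayed/correlated


def single_condition_map(
    condition_trials: np.ndarray,
    straight_trials: dict | list,
    paired: bool = True,
    smooth_diameter_px: float = 10.0,
    lowfreq_diameter_px: float = 120.0,
    contrast: tuple | None = None,
) -> SingleConditionResult:
    """Contrast one condition against the per-trial average of straight
    gratings (canonically the four orientations 0°, 45°, 90°, 135°)."""
    if isinstance(straight_trials, dict):
        arrs = list(straight_trials.values())
    else:
        arrs = list(straight_trials)
    if not arrs:
        raise ValueError("straight_trials must be nonempty")
    straight_avg = np.mean(np.stack(arrs, axis=0), axis=0)
    t, p = difference_statistic_map(condition_trials, straight_avg,
                                    paired=paired, contrast=contrast)
    filt = filter_map(t, smooth_diameter_px, lowfreq_diameter_px)
    filt.kind = "single_condition"
    return SingleConditionResult(t=t, p=p, filtered=filt)
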