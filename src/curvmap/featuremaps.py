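"""Orientation-preference angle maps and pinwheel detection.

The preferred orientation of a pixel is the half-angle of the vector sum
Σ r_θ·exp(i·2θ) over single-condition responses r_θ (rectified to
activation-positive).  Pinwheels — singularities around which the preferred
orientation cycles through 180° — are located by the winding of the doubled
angle around each 2×2 pixel plaquette: a net winding of ±180° marks a
pinwheel, its sign the chirality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "AngleMap",
    "orientation_angle_map",
    "detect_pinwheels",
    "pinwheel_vs_domain_report",
]


@dataclass
class AngleMap:
    """Per-pixel preferred orientation (degrees, [0, 180)) and vector strength."""

    angle_deg: np.ndarray
    magnitude: np.ndarray
    undefined: np.ndarray        # True where magnitude < tolerance
    source_orientations: tuple = ()


def orientation_angle_map(
    single_condition_maps: dict,
    activation_negative: bool = True,
    tol: float = 1e-12,
) -> AngleMap:
    """Vector-average orientation preference from per-orientation maps.

    ``single_condition_maps`` maps orientation (degrees) → 2-D response map.
    With ``activation_negative`` (the intrinsic-signal convention) responses
    are sign-flipped before rectification, so darker = stronger.  Pixels whose
    vector sum vanishes (e.g. equal responses at all orientations) are flagged
    undefined and get NaN angles.
    """
    if len(single_condition_maps) < 3:
        raise ValueError("need maps for at least 3 distinct orientations")
    thetas = sorted(float(t) % 180.0 for t in single_condition_maps)
    if len(set(thetas)) != len(single_condition_maps):
        raise ValueError("orientations must be distinct modulo 180")
    z = None
    for theta, values in single_condition_maps.items():
        v = np.asarray(getattr(values, "values", values), dtype=float)
        r = np.clip(-v if activation_negative else v, 0.0, None)
        term = r * np.exp(2j * np.deg2rad(float(theta)))
        z = term if z is None else z + term
    magnitude = np.abs(z)
    undefined = magnitude < tol
    angle = (np.rad2deg(np.angle(z)) / 2.0) % 180.0
    angle[undefined] = np.nan
    return AngleMap(angle, magnitude, undefined,
                    tuple(sorted(float(t) for t in single_condition_maps)))


def _wrap180(delta: np.ndarray) -> np.ndarray:
    """Wrap orientation differences to (−90, 90]."""
    m = np.mod(delta, 180.0)
    return np.where(m > 90.0, m - 180.0, m)


def detect_pinwheels(
    angle_map: np.ndarray | AngleMap,
    smooth_sigma: float = 2.0,
    periodic: bool = False,
) -> np.ndarray:
    """Pinwheel centers from plaquette winding of the doubled angle.

    Returns an ``(n, 3)`` array of (row, col, chirality ±1); sub-pixel centers
    sit at plaquette centroids.  ``smooth_sigma`` smooths the doubled-angle
    complex field first (suppresses noise-induced spurious charges; use 0 on
    noiseless maps).  With ``periodic`` the map is treated as a torus, on
    which the net topological charge is conserved (zero).
    """
    theta = np.asarray(getattr(angle_map, "angle_deg", angle_map), dtype=float)
    if smooth_sigma > 0:
        mode = "wrap" if periodic else "nearest"
        z = np.exp(2j * np.deg2rad(theta))
        z = (ndimage.gaussian_filter(z.real, smooth_sigma, mode=mode)
             + 1j * ndimage.gaussian_filter(z.imag, smooth_sigma, mode=mode))
        theta = np.rad2deg(np.angle(z)) / 2.0

    if periodic:
        a = theta
        b = np.roll(theta, -1, axis=1)
        c = np.roll(np.roll(theta, -1, axis=1), -1, axis=0)
        d = np.roll(theta, -1, axis=0)
    else:
        a = theta[:-1, :-1]
        b = theta[:-1, 1:]
        c = theta[1:, 1:]
        d = theta[1:, :-1]
    winding = (_wrap180(b - a) + _wrap180(c - b) + _wrap180(d - c) + _wrap180(a - d))
    rows, cols = np.nonzero(np.abs(winding) > 90.0)
    chirality = np.sign(winding[rows, cols])
    return np.column_stack([rows + 0.5, cols + 0.5, chirality]).reshape(-1, 3)


def pinwheel_vs_domain_report(
    pinwheels: np.ndarray,
    domain_masks: dict,
    pixel_size_mm: float = 1.0,
) -> pd.DataFrame:
    """Per pinwheel and domain class: inside/outside plus the distance (mm) to
    the nearest domain boundary.  With no domains of a class, every pinwheel
    is outside at infinite distance."""
    pinwheels = np.asarray(pinwheels, dtype=float).reshape(-1, 3)
    rows = []
    dist_maps = {}
    for name, mask in domain_masks.items():
        if hasattr(mask, "mask") and callable(mask.mask):
            mask = mask.mask()
        mask = np.asarray(mask, dtype=bool)
        if mask.any():
            dist_in = ndimage.distance_transform_edt(mask)
            dist_out = ndimage.distance_transform_edt(~mask)
            dist_maps[name] = (mask, dist_in, dist_out)
        else:
            dist_maps[name] = (mask, None, None)
    for i, (r, c, chi) in enumerate(pinwheels):
        ri = int(np.clip(round(r - 0.5), 0, next(iter(dist_maps.values()))[0].shape[0] - 1))
        ci = int(np.clip(round(c - 0.5), 0, next(iter(dist_maps.values()))[0].shape[1] - 1))
        for name, (mask, dist_in, dist_out) in dist_maps.items():
            if dist_in is None:
                inside, dist = False, np.inf
            else:
                inside = bool(mask[ri, ci])
                dist = float((dist_in if inside else dist_out)[ri, ci]) * pixel_size_mm
            rows.append({
                "pinwheel": i, "row": r, "col": c, "chirality": int(chi),
                "domain_class": name, "inside": inside,
                "distance_to_boundary_mm": dist,
            })
    return pd.DataFrame(rows)
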