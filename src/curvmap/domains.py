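"""Detection and morphometry of significant functional domains.

Domains are connected components (8-connected by default) of pixels passing a
per-pixel two-tailed t test (p < 0.01, with the activation sign — negative
ΔdR/R for preferred conditions under the intrinsic-signal convention).  An
optional one-way ANOVA + Tukey-Kramer gate replicates the additional check
applied to curvature domains.

Morphometry follows the "size = πR²" convention: R is the mean of the
semi-axes of the patch's second-moment (inertia) ellipse, the equivalent
diameter is 2R, and patches with equivalent diameter below 0.2 mm are
excluded as unreliable.  Activation centers are unweighted pixel centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

__all__ = [
    "DomainSet",
    "detect_domains",
    "filter_small_patches",
    "domain_morphometry",
    "overlap_percentage",
    "anova_tukey_gate",
]

DOMAIN_COLUMNS = [
    "id", "n_pixels", "area_mm2", "equivalent_diameter_mm",
    "centroid_row_mm", "centroid_col_mm", "mean_t",
]


@dataclass
class DomainSet:
    """Labeled significant patches plus per-domain morphometrics."""

    label_image: np.ndarray          # int grid, 0 = background
    domains: pd.DataFrame            # one row per label, DOMAIN_COLUMNS
    pixel_size_mm: float
    contrast: tuple | None = None
    alpha: float | None = None
    warning: str | None = None

    def __len__(self) -> int:
        return len(self.domains)

    def mask(self) -> np.ndarray:
        return self.label_image > 0

    def domain_mask(self, domain_id: int) -> np.ndarray:
        return self.label_image == domain_id

    def centroid_mm(self, domain_id: int) -> tuple[float, float]:
        row = self.domains.loc[self.domains["id"] == domain_id].iloc[0]
        return float(row["centroid_row_mm"]), float(row["centroid_col_mm"])


def _moment_radius_px(mask: np.ndarray) -> float:
    """Mean semi-axis of the second-moment ellipse of a pixel patch."""
    props = measure.regionprops(mask.astype(np.uint8))
    if not props:
        raise ValueError("empty mask")
    p = props[0]
    return (p.axis_major_length + p.axis_minor_length) / 4.0


def domain_morphometry(mask: np.ndarray, pixel_size_mm: float
                       ) -> tuple[float, float, tuple[float, float]]:
    """(area_mm² = πR², equivalent diameter 2R in mm, centroid in mm).

    R is the average of the second-moment ellipse semi-axes; the centroid is
    the unweighted pixel center of mass, in mm from the top-left pixel center.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    r_mm = _moment_radius_px(mask) * pixel_size_mm
    area = np.pi * r_mm**2
    rows, cols = np.nonzero(mask)
    centroid = (rows.mean() * pixel_size_mm, cols.mean() * pixel_size_mm)
    return area, 2.0 * r_mm, centroid


def _build_table(label_image: np.ndarray, t_values: np.ndarray | None,
                 pixel_size_mm: float) -> pd.DataFrame:
    rows = []
    for p in measure.regionprops(label_image):
        r_mm = (p.axis_major_length + p.axis_minor_length) / 4.0 * pixel_size_mm
        cy, cx = p.centroid
        mean_t = np.nan
        if t_values is not None:
            vals = t_values[label_image == p.label]
            finite = np.isfinite(vals)
            mean_t = float(vals[finite].mean()) if finite.any() else np.nan
        rows.append({
            "id": int(p.label),
            "n_pixels": int(p.area),
            "area_mm2": float(np.pi * r_mm**2),
            "equivalent_diameter_mm": float(2.0 * r_mm),
            "centroid_row_mm": float(cy * pixel_size_mm),
            "centroid_col_mm": float(cx * pixel_size_mm),
            "mean_t": mean_t,
        })
    return pd.DataFrame(rows, columns=DOMAIN_COLUMNS)


def detect_domains(
    t_map,
    p_map,
    sign: str = "negative",
    alpha: float = 0.01,
    pixel_size_mm: float | None = None,
    anova_groups: tuple | None = None,
    connectivity: int = 2,
    min_diameter_mm: float | None = None,
) -> DomainSet:
    """Label connected components of significant, correctly-signed pixels.

    ``t_map``/``p_map`` may be arrays or :class:`~curvmap.preprocess.ResponseMap`.
    ``anova_groups`` (optional) is ``(preferred_groups, reference_groups)``,
    each a list of ``(n_trials, rows, cols)`` arrays; pixels must additionally
    pass a one-way ANOVA (p < 0.05) with a Tukey-Kramer pairwise check in the
    preferred direction.  An empty result is a valid empty DomainSet.
    """
    t = np.asarray(getattr(t_map, "values", t_map), dtype=float)
    p = np.asarray(getattr(p_map, "values", p_map), dtype=float)
    if t.shape != p.shape:
        raise ValueError("t and p maps must share shape")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sign not in ("negative", "positive"):
        raise ValueError("sign must be 'negative' or 'positive'")
    if pixel_size_mm is None:
        pixel_size_mm = getattr(t_map, "provenance", {}).get("pixel_size_mm", 1.0)

    with np.errstate(invalid="ignore"):
        mask = (p < alpha) & ((t < 0) if sign == "negative" else (t > 0))
    mask &= np.isfinite(p)
    if anova_groups is not None:
        preferred, reference = anova_groups
        mask &= anova_tukey_gate(preferred, reference, sign=sign)

    labels = measure.label(mask, connectivity=connectivity)
    ds = DomainSet(
        label_image=labels,
        domains=_build_table(labels, t, pixel_size_mm),
        pixel_size_mm=pixel_size_mm,
        contrast=getattr(t_map, "contrast", None),
        alpha=alpha,
    )
    if min_diameter_mm is not None:
        ds = filter_small_patches(ds, min_diameter_mm)
    return ds


def filter_small_patches(domain_set: DomainSet,
                         min_diameter_mm: float = 0.2) -> DomainSet:
    """Drop patches with equivalent diameter < ``min_diameter_mm``; labels are
    recompacted to 1..K."""
    keep = domain_set.domains[
        domain_set.domains["equivalent_diameter_mm"] >= min_diameter_mm
    ]
    old_labels = keep["id"].to_numpy()
    relabel = np.zeros(int(domain_set.label_image.max()) + 1, dtype=domain_set.label_image.dtype)
    for new, old in enumerate(old_labels, start=1):
        relabel[old] = new
    new_image = relabel[domain_set.label_image]
    table = keep.copy().reset_index(drop=True)
    table["id"] = np.arange(1, len(table) + 1)
    return DomainSet(
        label_image=new_image, domains=table,
        pixel_size_mm=domain_set.pixel_size_mm,
        contrast=domain_set.contrast, alpha=domain_set.alpha,
    )


def overlap_percentage(mask_a: np.ndarray, mask_b: np.ndarray,
                       mode: str = "colored") -> float:
    """Overlap of two pixel sets as a percentage: 100·|A∩B| / |A∪B|.

    Reported against "all colored pixels" (the union of the two sets); the
    ``union`` mode is the same quantity under its IoU name.  Two empty masks
    give 0 with a warning.
    """
    if mode not in ("union", "colored"):
        raise ValueError("mode must be 'union' or 'colored'")
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    union = (a | b).sum()
    if union == 0:
        warnings.warn("both masks empty; overlap defined as 0", stacklevel=2)
        return 0.0
    return 100.0 * (a & b).sum() / union


def anova_tukey_gate(
    preferred_groups,
    reference_groups,
    alpha: float = 0.05,
    sign: str = "negative",
    rule: str = "any",
) -> np.ndarray:
    """Per-pixel one-way ANOVA across all groups (p < ``alpha``) plus a
    Tukey-Kramer pairwise check that preferred groups differ from reference
    groups in the activation direction.

    ``rule='any'`` (default) requires at least one significant
    preferred-vs-reference pair; ``'all'`` requires every pair.
    """
    if sign not in ("negative", "positive"):
        raise ValueError("sign must be 'negative' or 'positive'")
    pref = [np.asarray(g, dtype=float) for g in preferred_groups]
    ref = [np.asarray(g, dtype=float) for g in reference_groups]
    groups = pref + ref
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.shape[0] for g in groups], dtype=float)
    n_tot = ns.sum()
    means = np.stack([g.mean(axis=0) for g in groups])
    sses = np.stack([g.var(axis=0, ddof=0) * g.shape[0] for g in groups])
    grand = np.tensordot(ns, means, axes=(0, 0)) / n_tot
    ssb = np.tensordot(ns, (means - grand[None]) ** 2, axes=(0, 0))
    ssw = sses.sum(axis=0)
    df_b, df_w = k - 1, int(n_tot) - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p_anova = stats.f.sf(f, df_b, df_w)
    gate = p_anova < alpha

    mse = ssw / df_w
    q_crit = stats.studentized_range.isf(alpha, k, df_w)
    passed = None
    for i, gp in enumerate(pref):
        for j, gr in enumerate(ref):
            se = np.sqrt(mse / 2.0 * (1.0 / gp.shape[0] + 1.0 / gr.shape[0]))
            with np.errstate(divide="ignore", invalid="ignore"):
                q = (means[i] - means[len(pref) + j]) / se
            ok = (q <= -q_crit) if sign == "negative" else (q >= q_crit)
            passed = ok if passed is None else (
                (passed | ok) if rule == "any" else (passed & ok))
    return gate & passed
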