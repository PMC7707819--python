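"""Straight→curved domain progressions: nearest-domain chains and centroid
distances as a function of curvature degree.

Starting from a straight-orientation domain's activation center, the nearest
(Euclidean, cortical mm) curvature domain of each degree condition is
selected; the distance from the straight center to each selected center,
ordered by curvature ratio, characterizes whether the representation shifts
spatially with curvature degree.  A progression is flagged "shifting" when
the Spearman rank correlation of distance vs. ratio exceeds a configurable
threshold (a reporting convenience, not an inferential claim).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .domains import DomainSet

__all__ = [
    "ProgressionRecord",
    "nearest_curvature_domains",
    "progression_distances",
    "average_progression",
]


@dataclass
class ProgressionRecord:
    """One straight domain and its nearest curvature domain per ratio."""

    straight_centroid_mm: tuple[float, float]
    ratios: tuple[float, ...]
    domain_ids: tuple[int | None, ...]
    centroids_mm: tuple[tuple[float, float] | None, ...]
    straight_id: int | None = None
    orientation_class: str | None = None

    def __post_init__(self):
        r = [x for x in self.ratios]
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("ratios must be strictly increasing")

    @property
    def distances_mm(self) -> np.ndarray:
        sr, sc = self.straight_centroid_mm
        out = []
        for cen in self.centroids_mm:
            if cen is None:
                out.append(np.nan)
            else:
                out.append(float(np.hypot(cen[0] - sr, cen[1] - sc)))
        return np.array(out)


def nearest_curvature_domains(
    straight_centroid_mm: tuple[float, float],
    domain_sets_by_ratio: dict[float, DomainSet],
    straight_id: int | None = None,
    orientation_class: str | None = None,
) -> ProgressionRecord:
    """For each curvature ratio, select the domain whose centroid is nearest
    to the straight domain's centroid (ties broken by lower label id).

    Ratios whose DomainSet is empty are flagged missing (None); if every
    ratio is empty a ``ValueError`` is raised.
    """
    ratios = tuple(sorted(domain_sets_by_ratio))
    ids, cents = [], []
    sr, sc = straight_centroid_mm
    any_found = False
    for ratio in ratios:
        ds = domain_sets_by_ratio[ratio]
        if len(ds) == 0:
            ids.append(None)
            cents.append(None)
            continue
        tbl = ds.domains
        d2 = (tbl["centroid_row_mm"] - sr) ** 2 + (tbl["centroid_col_mm"] - sc) ** 2
        # stable nearest with lower-id tie-break: sort by (distance, id)
        order = tbl.assign(_d2=d2).sort_values(["_d2", "id"], kind="mergesort")
        best = order.iloc[0]
        ids.append(int(best["id"]))
        cents.append((float(best["centroid_row_mm"]), float(best["centroid_col_mm"])))
        any_found = True
    if not any_found:
        raise ValueError("every ratio's DomainSet is empty")
    return ProgressionRecord(
        straight_centroid_mm=tuple(straight_centroid_mm), ratios=ratios,
        domain_ids=tuple(ids), centroids_mm=tuple(cents),
        straight_id=straight_id, orientation_class=orientation_class,
    )


def progression_distances(
    record: ProgressionRecord,
    shifting_threshold: float = 0.5,
) -> dict:
    """Distances per ratio plus monotonicity statistics.

    Returns ``{'ratios', 'distances_mm', 'spearman_rho', 'spearman_p',
    'shifting'}``; ``shifting`` is True when distance increases with ratio
    (Spearman rho > threshold).  Missing ratios are excluded pairwise.
    """
    dist = record.distances_mm
    ok = np.isfinite(dist)
    if ok.sum() < 2:
        raise ValueError("need at least 2 ratios with domains")
    ratios = np.asarray(record.ratios, dtype=float)[ok]
    d = dist[ok]
    if np.allclose(d, d[0]):
        rho, pval = 0.0, 1.0
    else:
        rho, pval = stats.spearmanr(ratios, d)
    return {
        "ratios": ratios,
        "distances_mm": d,
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
        "shifting": bool(rho > shifting_threshold),
    }


def average_progression(records) -> pd.DataFrame:
    """Mean ± SD (sample, ddof=1) distance per ratio over progression records.

    Missing ratios are excluded pairwise; a ratio observed once has SD 0.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    per_ratio: dict[float, list[float]] = {}
    for rec in records:
        for ratio, dist in zip(rec.ratios, rec.distances_mm):
            if np.isfinite(dist):
                per_ratio.setdefault(float(ratio), []).append(float(dist))
    rows = []
    for ratio in sorted(per_ratio):
        vals = np.array(per_ratio[ratio])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"ratio": ratio, "mean_distance_mm": float(vals.mean()),
                     "sd_distance_mm": sd, "n": len(vals)})
    return pd.DataFrame(rows)
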