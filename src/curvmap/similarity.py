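"""Map-similarity analysis: ROI-restricted cross-correlation between
single-condition maps and its relation to curvature-degree difference.

Similarity between two condition maps is the Pearson correlation over the
pixels of a region of interest — canonically the union of pixels
significantly activated (vs. blank) by the curvature conditions.  Relating
the pairwise correlations to the ordinal curvature-degree difference of the
two conditions (condition rank stands in for relative curvature degree)
quantifies the graded similarity structure of the degree map.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import difference_statistic_map

__all__ = [
    "map_correlation",
    "correlation_matrix",
    "degree_difference_regression",
    "curvature_roi",
]


def _values(m) -> np.ndarray:
    return np.asarray(getattr(m, "values", m), dtype=float)


def map_correlation(map_a, map_b, roi: np.ndarray) -> float:
    """Pearson correlation between two maps over ROI pixels only.

    Returns NaN (with a warning) if either map has zero variance over the ROI.
    """
    a, b = _values(map_a), _values(map_b)
    roi = np.asarray(roi, dtype=bool)
    if a.shape != b.shape or a.shape != roi.shape:
        raise ValueError("maps and roi must share shape")
    sel = roi & np.isfinite(a) & np.isfinite(b)
    if not sel.any():
        raise ValueError("roi is empty")
    x, y = a[sel], b[sel]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance over ROI; correlation undefined", stacklevel=2)
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def correlation_matrix(maps, roi: np.ndarray, labels=None) -> pd.DataFrame:
    """All pairwise ROI-restricted correlations as a labeled K×K DataFrame.

    Undefined entries (zero-variance maps) propagate as NaN.
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    if labels is None:
        labels = [f"map{i}" for i in range(len(maps))]
    k = len(maps)
    out = np.ones((k, k))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(k):
            for j in range(i + 1, k):
                out[i, j] = out[j, i] = map_correlation(maps[i], maps[j], roi)
        for i in range(k):
            out[i, i] = map_correlation(maps[i], maps[i], roi)
    return pd.DataFrame(out, index=list(labels), columns=list(labels))


def curvature_roi(curvature_trials: dict, blank_trials: np.ndarray,
                  alpha: float = 0.01) -> np.ndarray:
    """Union of pixels significantly activated vs. blank (negative dR/R,
    p < alpha) across the given curvature conditions."""
    roi = None
    for trials in curvature_trials.values():
        t, p = difference_statistic_map(trials, blank_trials, paired=True)
        sig = (p.values < alpha) & (t.values < 0)
        roi = sig if roi is None else (roi | sig)
    if roi is None:
        raise ValueError("curvature_trials must be nonempty")
    return roi


def degree_difference_regression(
    matrix: pd.DataFrame,
    degree_indices: dict,
    min_points: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Regress correlation against |degree difference| per reference condition.

    ``degree_indices`` maps condition label → ordinal curvature-degree rank;
    labels absent from the mapping (e.g. straight conditions) are excluded.
    Returns a per-reference table (slope, intercept, r², p, n; references with
    fewer than ``min_points`` points are flagged and excluded from pooling)
    and a pooled fit over all pairs.
    """
    labels = [l for l in matrix.index if l in degree_indices]
    if len(labels) < 2:
        raise ValueError("need at least two conditions with degree indices")
    rows = []
    pooled_x, pooled_y = [], []
    for ref in labels:
        x, y = [], []
        for other in labels:
            if other == ref:
                continue
            r = matrix.loc[ref, other]
            if np.isfinite(r):
                x.append(abs(degree_indices[ref] - degree_indices[other]))
                y.append(float(r))
        flagged = len(x) < min_points or len(set(x)) < 2
        if flagged:
            rows.append({"reference": ref, "slope": np.nan, "intercept": np.nan,
                         "r2": np.nan, "p": np.nan, "n": len(x), "flagged": True})
            continue
        fit = stats.linregress(x, y)
        rows.append({"reference": ref, "slope": fit.slope, "intercept": fit.intercept,
                     "r2": fit.rvalue**2, "p": fit.pvalue, "n": len(x),
                     "flagged": False})
        pooled_x.extend(x)
        pooled_y.extend(y)
    table = pd.DataFrame(rows)
    if len(pooled_x) >= 2 and len(set(pooled_x)) >= 2:
        fit = stats.linregress(pooled_x, pooled_y)
        pooled = {"slope": fit.slope, "intercept": fit.intercept,
                  "r2": fit.rvalue**2, "p": fit.pvalue, "n": len(pooled_x)}
    else:
        pooled = {"slope": np.nan, "intercept": np.nan, "r2": np.nan,
                  "p": np.nan, "n": len(pooled_x)}
    return table, pooled
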