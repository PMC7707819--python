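"""Domain-averaged response timecourses and nonparametric comparisons.

A domain timecourse is the per-frame dR/R averaged over the domain's
significant pixels (gated, when a blank contrast is supplied, at p < 0.01
vs. blank) and then over trials, with the SEM taken over trials.  Two
timecourses are compared with a Wilcoxon rank-sum test on the per-frame
values within frames 9–18 (1-based) — the procedure used for
intrinsic-signal amplitude comparisons, applied here as stated even though
successive frames are autocorrelated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import frame_drr

__all__ = [
    "Timecourse",
    "extract_domain_timecourse",
    "compare_timecourses",
    "amplitude_summary",
    "DEFAULT_FRAME_WINDOW",
]

DEFAULT_FRAME_WINDOW = (9, 18)  # 1-based inclusive


@dataclass
class Timecourse:
    """Domain-averaged dR/R per frame with trial SEM."""

    mean: np.ndarray           # (n_frames,)
    sem: np.ndarray            # (n_frames,)
    n_pixels: int
    n_trials: int
    condition: str | None = None
    mask_id: str | None = None

    @property
    def n_frames(self) -> int:
        return self.mean.size

    def window_mean(self, frame_window=DEFAULT_FRAME_WINDOW) -> float:
        lo, hi = _clip_window(frame_window, self.n_frames)
        return float(self.mean[lo - 1:hi].mean())

    def window_amplitude(self, frame_window=DEFAULT_FRAME_WINDOW) -> float:
        """Response amplitude: negated window-mean dR/R (activation darkens)."""
        return -self.window_mean(frame_window)


def _clip_window(frame_window, n_frames) -> tuple[int, int]:
    lo, hi = int(frame_window[0]), int(frame_window[1])
    if lo < 1 or lo >= hi:
        raise ValueError(f"bad frame window {frame_window}")
    if lo > n_frames:
        raise ValueError(f"frame window {frame_window} outside {n_frames} frames")
    if hi > n_frames:
        warnings.warn(
            f"frame window {frame_window} clipped to ({lo}, {n_frames}) "
            f"for a {n_frames}-frame session", stacklevel=3)
        hi = n_frames
    return lo, hi


def extract_domain_timecourse(
    session,
    mask: np.ndarray,
    condition: str,
    gate_p: np.ndarray | None = None,
    gate_alpha: float = 0.01,
    mask_id: str | None = None,
) -> Timecourse:
    """Average the per-pixel dR/R timecourse over a domain mask.

    ``gate_p`` (optional, e.g. a condition-vs-blank p map) restricts the mask
    to significant pixels at ``gate_alpha``; an empty gated mask raises,
    naming the gate.  Averaging over pixels then trials (equal weights) —
    identical to the reverse order.
    """
    mask = np.asarray(mask, dtype=bool)
    if gate_p is not None:
        p = np.asarray(getattr(gate_p, "values", gate_p), dtype=float)
        mask = mask & (p < gate_alpha)
        if not mask.any():
            raise ValueError(
                f"mask empty after significance gate (p < {gate_alpha} vs. blank)")
    if not mask.any():
        raise ValueError("mask is empty")
    stack = session.stack(condition)             # (trials, frames, rows, cols)
    drr = frame_drr(stack, n_baseline_frames=session.n_prestim_frames)
    traces = drr[:, :, mask].mean(axis=2)        # (trials, frames)
    mean = traces.mean(axis=0)
    n_tr = traces.shape[0]
    sem = traces.std(axis=0, ddof=1) / np.sqrt(n_tr) if n_tr > 1 else np.zeros_like(mean)
    return Timecourse(mean=mean, sem=sem, n_pixels=int(mask.sum()),
                      n_trials=n_tr, condition=condition, mask_id=mask_id)


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float | None:
    """Two-sided exact rank-sum p (via the Mann-Whitney exact distribution);
    None when ties make the exact distribution inapplicable."""
    combined = np.concatenate([x, y])
    if len(np.unique(combined)) < combined.size:
        return None
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    return float(res.pvalue)


def compare_timecourses(
    tc_a: Timecourse,
    tc_b: Timecourse,
    frame_window=DEFAULT_FRAME_WINDOW,
) -> dict:
    """Wilcoxon rank-sum on the per-frame values within the frame window.

    Exact p when there are no ties (and both groups are small enough for the
    exact distribution); asymptotic otherwise.  Returns the two-sided p and
    the median difference a − b over the window.
    """
    lo_a, hi_a = _clip_window(frame_window, tc_a.n_frames)
    lo_b, hi_b = _clip_window(frame_window, tc_b.n_frames)
    x = np.asarray(tc_a.mean[lo_a - 1:hi_a], dtype=float)
    y = np.asarray(tc_b.mean[lo_b - 1:hi_b], dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 frames per group in the window")
    p = None
    if x.size <= 25 and y.size <= 25:
        p = _rank_sum_exact_p(x, y)
    if p is None:
        if np.array_equal(x, y):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="asymptotic").pvalue)
    return {
        "p": p,
        "median_difference": float(np.median(x) - np.median(y)),
        "n_frames": (x.size, y.size),
    }


def amplitude_summary(
    timecourses: dict,
    preferred: dict | None = None,
    frame_window=DEFAULT_FRAME_WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window amplitudes per (domain class, stimulus class) plus pairwise
    stimulus-class comparisons within each domain class.

    ``timecourses`` maps ``(domain_class, stimulus_class)`` → Timecourse.
    ``preferred`` (optional) maps domain class → its preferred stimulus
    class; comparisons are then restricted to preferred vs. each other class.
    """
    rows = []
    for (dclass, sclass), tc in timecourses.items():
        rows.append({
            "domain_class": dclass, "stimulus_class": sclass,
            "amplitude": tc.window_amplitude(frame_window),
            "n_pixels": tc.n_pixels, "n_trials": tc.n_trials,
        })
    table = pd.DataFrame(rows)

    contrasts = []
    for dclass in table["domain_class"].unique():
        classes = [s for (d, s) in timecourses if d == dclass]
        if preferred is not None and dclass in preferred:
            pairs = [(preferred[dclass], s) for s in classes
                     if s != preferred[dclass]]
        else:
            pairs = list(combinations(classes, 2))
        for s1, s2 in pairs:
            res = compare_timecourses(timecourses[(dclass, s1)],
                                      timecourses[(dclass, s2)], frame_window)
            contrasts.append({
                "domain_class": dclass, "stimulus_a": s1, "stimulus_b": s2,
                "p": res["p"],
                "amplitude_difference":
                    timecourses[(dclass, s1)].window_amplitude(frame_window)
                    - timecourses[(dclass, s2)].window_amplitude(frame_window),
            })
    return table, pd.DataFrame(contrasts)
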