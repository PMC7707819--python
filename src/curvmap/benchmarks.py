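"""Simulation studies validating the pipeline against planted ground truth.

Each study runs one of the standard scenarios end to end — simulate, map,
detect, measure — and returns the recovery metrics as a plain dict.  The test
suite asserts on these metrics; ``scripts/acceptance.py`` reports them.

All randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

from . import scenarios as sc
from .domains import detect_domains, overlap_percentage
from .featuremaps import detect_pinwheels
from .preprocess import difference_statistic_map
from .progression import (average_progression, nearest_curvature_domains,
                          progression_distances)
from .similarity import correlation_matrix, curvature_roi
from .stimuli import (apply_block_permutation, curved_grating_image,
                      scramble_permutation, straight_grating_image)
from .synth import CortexParams, make_cortical_model
from .timecourses import compare_timecourses, extract_domain_timecourse

__all__ = [
    "paired_t_oracle_study", "null_calibration_study",
    "domain_recovery_study", "degree_similarity_study",
    "orientation_pair_study", "pinwheel_study", "progression_study",
    "timecourse_study", "stimulus_invariant_study",
]

STRAIGHT_IDS = ["s0", "s45", "s90", "s135"]


def _loop_paired_t(a, b):
    """Brute-force per-pixel paired t, kept independent of the vectorized
    implementation."""
    n, h, w = a.shape
    t = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            d = [a[k, r, c] - b[k, r, c] for k in range(n)]
            m = sum(d) / n
            s = (sum((x - m) ** 2 for x in d) / (n - 1)) ** 0.5
            t[r, c] = m * n**0.5 / s
    return t


def paired_t_oracle_study(seed: int, n_instances: int = 100) -> dict:
    """Vectorized paired-t maps vs. a scalar loop on random 8×8, N=5 data."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    worst_sym = 0.0
    for _ in range(n_instances):
        a = rng.normal(size=(5, 8, 8))
        b = rng.normal(size=(5, 8, 8))
        t_map, _ = difference_statistic_map(a, b)
        worst = max(worst, float(np.abs(t_map.values - _loop_paired_t(a, b)).max()))
        t_swap, _ = difference_statistic_map(b, a)
        worst_sym = max(worst_sym,
                        float(np.abs(t_map.values + t_swap.values).max()))
    return {"max_abs_t_error": worst, "max_antisymmetry_error": worst_sym,
            "n_instances": n_instances}


def null_calibration_study(seed: int, n_seeds: int = 20,
                           alpha: float = 0.01) -> dict:
    """False-positive calibration on noise-only sessions (128², 30 trials)."""
    curved_ids = [f"c5_{o}" for o in sc.CURVE_ORIENTS]
    fracs, false_domains, n_px = [], [], 0
    for k in range(n_seeds):
        _, sess = sc.null_scenario(seed=seed + 17 * k)
        resp = sc.trial_responses_by_condition(sess)
        t, p = sc.curvature_vs_straight_maps(resp, curved_ids, STRAIGHT_IDS)
        fracs.append(float((p.values < alpha).mean()))
        ds = detect_domains(t, p, sign="negative", alpha=alpha,
                            pixel_size_mm=sess.pixel_size_mm,
                            min_diameter_mm=0.2)
        false_domains.append(len(ds))
        n_px = p.values.size
        del sess, resp
    return {
        "significant_fraction": float(np.mean(fracs)),
        "false_domains_per_10k_px": float(np.mean(false_domains) / n_px * 1e4),
        "n_seeds": n_seeds,
        "n_pixels": n_px,
    }


def domain_recovery_study(seed: int) -> dict:
    """Dice and size recovery of planted curvature domains (0.02 % amplitude,
    default noise, 30 trials) under the curved-vs-straight contrast."""
    model, sess = sc.domain_recovery_scenario(seed=seed)
    resp = sc.trial_responses_by_condition(sess)
    curved_ids = [f"c5_{o}" for o in sc.CURVE_ORIENTS]
    t, p = sc.curvature_vs_straight_maps(resp, curved_ids, STRAIGHT_IDS)
    ds = detect_domains(t, p, sign="negative", alpha=0.01,
                        pixel_size_mm=sess.pixel_size_mm, min_diameter_mm=0.2)
    detected = ds.mask()
    planted = model.domain_mask("curvature")
    dice = 2.0 * (detected & planted).sum() / (detected.sum() + planted.sum())
    det_diam = float(ds.domains["equivalent_diameter_mm"].mean())
    planted_diams = [2 * d.radius_px * model.pixel_size_mm
                     for d in model.domains if d.kind == "curvature"]
    plant_diam = float(np.mean(planted_diams))
    return {
        "dice": float(dice),
        "detected_mean_diameter_mm": det_diam,
        "planted_mean_diameter_mm": plant_diam,
        "diameter_error_pct": float(100 * abs(det_diam - plant_diam) / plant_diam),
        "n_detected": len(ds),
        "n_planted": len(planted_diams),
    }


def degree_similarity_study(seed: int) -> dict:
    """Similarity-vs-degree structure on the 12-curvature + straight
    battery with planted degree progressions."""
    model, sess = sc.degree_map_scenario(seed=seed)
    resp = sc.trial_responses_by_condition(sess)
    curved_ids = [f"c{r:g}_{o}" for o in ("up", "down") for r in sc.DEGREE_SERIES]
    roi = curvature_roi({c: resp[c] for c in curved_ids}, resp["blank"])
    maps = sc.single_condition_maps(resp, curved_ids + STRAIGHT_IDS, STRAIGHT_IDS)
    labels = curved_ids + STRAIGHT_IDS
    mat = correlation_matrix([maps[c].filtered for c in labels], roi,
                             labels=labels)
    spearmans = {}
    for orient in ("up", "down"):
        labs = [f"c{r:g}_{orient}" for r in sc.DEGREE_SERIES]
        x, y = [], []
        for i, j in combinations(range(len(labs)), 2):
            x.append(j - i)
            y.append(float(mat.loc[labs[i], labs[j]]))
        spearmans[orient] = float(stats.spearmanr(x, y).statistic)
    straight_min_rows = sum(
        mat.loc[c].drop(c).idxmin() in STRAIGHT_IDS for c in curved_ids)
    return {
        "spearman_up": spearmans["up"],
        "spearman_down": spearmans["down"],
        "rows_with_straight_minimum": int(straight_min_rows),
        "n_curved_rows": len(curved_ids),
        "roi_pixels": int(roi.sum()),
    }


def orientation_pair_study(seed: int, planted_iou: float = 0.2) -> dict:
    """Recovery of the planted opposing-orientation subdomain overlap."""
    model, sess = sc.orientation_pair_scenario(seed=seed,
                                               planted_iou=planted_iou)
    resp = sc.trial_responses_by_condition(sess)
    masks = {}
    for cid in ("c5_up", "c5_down"):
        res = sc.single_condition_maps(resp, [cid], STRAIGHT_IDS)[cid]
        ds = detect_domains(res.t, res.p, sign="negative", alpha=0.01,
                            pixel_size_mm=sess.pixel_size_mm,
                            min_diameter_mm=0.2)
        masks[cid] = ds.mask()
    measured = overlap_percentage(masks["c5_up"], masks["c5_down"])
    up = np.zeros(model.shape, dtype=bool)
    down = np.zeros(model.shape, dtype=bool)
    for d in model.domains:
        if d.kind != "curvature":
            continue
        if d.phi_deg == 90.0:
            up |= d.mask(model.shape)
        elif d.phi_deg == 270.0:
            down |= d.mask(model.shape)
    planted = overlap_percentage(up, down)
    return {
        "planted_overlap_pct": float(planted),
        "measured_overlap_pct": float(measured),
        "overlap_error_points": float(abs(measured - planted)),
    }


def pinwheel_study(seed: int, n_models: int = 20) -> dict:
    """Pinwheel detection vs. generator ground truth over synthetic maps,
    plus topological-charge conservation on a periodic fixture."""
    count_err = 0
    worst_loc = 0.0
    for k in range(n_models):
        model = make_cortical_model(CortexParams(shape=(96, 96)),
                                    seed=seed + 31 * k)
        pins = detect_pinwheels(model.orientation_angle_map, smooth_sigma=0)
        truth = model.pinwheel_centers
        count_err += abs(len(pins) - len(truth))
        if len(pins) == len(truth) and len(pins):
            # match detections to ground truth greedily by distance
            d = np.hypot(pins[:, None, 0] - truth[None, :, 0],
                         pins[:, None, 1] - truth[None, :, 1])
            worst_loc = max(worst_loc, float(d.min(axis=1).max()))
    # periodic fixture: band-pass complex noise on a torus
    rng = np.random.default_rng(seed + 999)
    z = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
    fr = np.fft.fftfreq(64)[:, None]
    fc = np.fft.fftfreq(64)[None, :]
    kk = np.hypot(fr, fc)
    band = np.exp(-((kk - 0.08) ** 2) / (2 * 0.03**2))
    ang = (np.rad2deg(np.angle(np.fft.ifft2(np.fft.fft2(z) * band))) / 2) % 180
    torus = detect_pinwheels(ang, smooth_sigma=0, periodic=True)
    return {
        "count_error_total": int(count_err),
        "max_localization_error_px": worst_loc,
        "net_chirality_on_torus": int(torus[:, 2].sum()) if len(torus) else 0,
        "n_models": n_models,
    }


def progression_study(seed: int, n_sessions: int = 4,
                      n_null_layouts: int = 200) -> dict:
    """Spacing recovery for planted straight→curved progressions, plus the
    null rate of the 'shifting' flag on independent layouts."""
    records = []
    for k in range(n_sessions):
        _, sess = sc.progression_scenario(seed=seed + 13 * k)
        resp = sc.trial_responses_by_condition(sess)
        cond_ids = [f"c{r:g}_up" for r in sc.PROGRESSION_RATIOS]
        maps = sc.single_condition_maps(resp, cond_ids + ["s0"], STRAIGHT_IDS)
        dsets = {}
        for ratio, cid in zip(sc.PROGRESSION_RATIOS, cond_ids):
            dsets[ratio] = detect_domains(
                maps[cid].t, maps[cid].p, sign="negative", alpha=0.01,
                pixel_size_mm=sess.pixel_size_mm, min_diameter_mm=0.2)
        straight = detect_domains(maps["s0"].t, maps["s0"].p, sign="negative",
                                  alpha=0.01, pixel_size_mm=sess.pixel_size_mm,
                                  min_diameter_mm=0.2)
        for _, row in straight.domains.iterrows():
            records.append(nearest_curvature_domains(
                (row["centroid_row_mm"], row["centroid_col_mm"]), dsets))
        del sess, resp
    avg = average_progression(records)
    dist = avg["mean_distance_mm"].to_numpy()
    spacing = float(np.mean(np.diff(dist)))

    # null: domains placed independently of the straight centroid
    from .domains import DomainSet
    import pandas as pd

    rng = np.random.default_rng(seed + 5)
    flags = []
    for _ in range(n_null_layouts):
        dsets = {}
        for ratio in sc.PROGRESSION_RATIOS:
            pts = rng.uniform(0, 3.2, size=(4, 2))
            rows = [{"id": i + 1, "n_pixels": 10, "area_mm2": 0.05,
                     "equivalent_diameter_mm": 0.25,
                     "centroid_row_mm": p[0], "centroid_col_mm": p[1],
                     "mean_t": -5.0} for i, p in enumerate(pts)]
            dsets[ratio] = DomainSet(np.zeros((4, 4), int),
                                     pd.DataFrame(rows), 0.025)
        rec = nearest_curvature_domains(tuple(rng.uniform(0, 3.2, 2)), dsets)
        flags.append(progression_distances(rec)["shifting"])
    return {
        "mean_spacing_mm": spacing,
        "planted_spacing_mm": 0.2,
        "spacing_error_pct": float(100 * abs(spacing - 0.2) / 0.2),
        "mean_distance_monotone": bool((np.diff(dist) > 0).all()),
        "n_progressions": len(records),
        "null_shifting_fraction": float(np.mean(flags)),
    }


def timecourse_study(seed: int) -> dict:
    """Forward-model recovery of the curved-vs-straight timecourse contrast
    at a planted curvature domain, with the Wilcoxon comparison."""
    from .synth import frame_onset_times, hemodynamic_kernel

    model, sess = sc.domain_recovery_scenario(seed=seed, n_domains=4)
    dom = [d for d in model.domains if d.kind == "curvature"][0]
    mask = dom.mask(model.shape)
    orient = {90.0: "up", 270.0: "down", 0.0: "right", 180.0: "left"}[dom.phi_deg]
    tc_curved = extract_domain_timecourse(sess, mask, f"c5_{orient}")
    tc_straight = extract_domain_timecourse(sess, mask, "s0")
    window = (9, 18)
    measured = tc_curved.window_amplitude(window) \
        - tc_straight.window_amplitude(window)
    # planted contrast: amplitude × window kernel mean × tuning difference
    from .synth import tuning_response_map

    t_rel = frame_onset_times(sess.n_frames, sess.frame_rate_hz,
                              sess.n_prestim_frames)
    kbar = hemodynamic_kernel(t_rel)[window[0] - 1:window[1]].mean()
    resp_c = tuning_response_map(model, sess.condition_table[f"c5_{orient}"])
    resp_s = tuning_response_map(model, sess.condition_table["s0"])
    planted = float((resp_c[mask] - resp_s[mask]).mean() * kbar)
    res = compare_timecourses(tc_curved, tc_straight, window)
    return {
        "measured_contrast": float(measured),
        "planted_contrast": planted,
        "contrast_error_pct": float(100 * abs(measured - planted) / planted),
        "wilcoxon_p": float(res["p"]),
    }


def stimulus_invariant_study(seed: int = 0) -> dict:
    """Geometric invariants of the stimulus set (odd grid puts a pixel
    exactly on the central axis)."""
    pitch = 4.0 / 401
    p2 = curved_grating_image(2, "up", 1.0, 4.0, pitch)[:, 200]
    p5 = curved_grating_image(5, "up", 1.0, 4.0, pitch)[:, 200]
    c0 = curved_grating_image(0.0, "up", 1.0, 4.0, pitch, t=0.2)
    s0 = straight_grating_image(0.0, 1.0, 4.0, pitch, t=0.2)
    up = curved_grating_image(5, "up", 1.0, 4.0, pitch)
    down = curved_grating_image(5, "down", 1.0, 4.0, pitch)
    img = curved_grating_image(5, "up", 1.0, 4.0, 0.05)[:80, :80]
    perm = scramble_permutation(64, seed=seed)
    scr = apply_block_permutation(img, perm)
    return {
        "central_profile_max_diff": float(np.abs(p2 - p5).max()),
        "ratio0_vs_straight_max_diff": float(np.abs(c0 - s0).max()),
        "mirror_symmetry_max_diff": float(np.abs(np.flipud(up) - down).max()),
        "scramble_histogram_exact": bool(
            np.array_equal(np.sort(scr.ravel()), np.sort(img.ravel()))),
    }
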