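"""Standard simulated experiments: condition batteries and model
configurations used throughout the examples, tests and the results script.

Each scenario pins the study conditions it emulates — grid and pixel size,
trial counts (≥30 per condition), stimulus batteries (curvature ratios ×
curve orientations plus the four straight orientations and a blank), domain
sizes (0.2–0.5 mm), response amplitudes (0.01–0.03 %) — and the tuning widths
appropriate for what it probes:

* ``domain_recovery``  — hard-edged curvature domains at a fixed 0.02 %
  amplitude, for detection/morphometry parameter recovery.
* ``null``             — the same acquisition with no planted structure, for
  false-positive calibration.
* ``degree_map``       — paired up/down progressions over a 6-ratio series
  with broad degree tuning (σ_d = 1.0), producing the graded
  similarity-vs-degree structure of the curvature map.
* ``orientation_pair`` — opposing-orientation subdomain pairs at a planted
  IoU, for overlap recovery.
* ``progression``      — straight→curved chains with narrow degree tuning
  (σ_d = 0.15, so each ratio condition activates only its own domains and
  centroids stay identifiable) for spacing recovery; chains are kept farther
  apart than their length, and a many-progression study aggregates records
  over several simulated sessions.
"""

from __future__ import annotations

import numpy as np

from .preprocess import (SingleConditionResult, difference_statistic_map,
                         single_condition_map, trial_response)
from .stimuli import StimulusSpec
from .synth import (CortexParams, CorticalModel, ImagingSession, NoiseSpec,
                    make_cortical_model, simulate_session)

__all__ = [
    "straight_specs", "curved_specs", "curvature_battery",
    "trial_responses_by_condition", "average_groups",
    "curvature_vs_straight_maps", "single_condition_maps",
    "null_scenario", "domain_recovery_scenario", "degree_map_scenario",
    "orientation_pair_scenario", "progression_scenario",
]

STRAIGHT_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)
CURVE_ORIENTS = ("up", "down", "left", "right")


def make_model_with_retry(params: CortexParams, seed: int,
                          max_attempts: int = 25) -> CorticalModel:
    """Build a model, shifting the placement stream on the rare seeds whose
    rejection sampling cannot fit every requested domain."""
    from .synth import PlacementError

    for k in range(max_attempts):
        try:
            return make_cortical_model(params, seed=seed + 100_000 * k)
        except PlacementError:
            continue
    raise PlacementError(
        f"placement failed for {max_attempts} consecutive derived seeds")


def straight_specs(sf_cpd: float = 1.0) -> dict[str, StimulusSpec]:
    return {
        f"s{int(th)}": StimulusSpec("straight_grating", 0.0, th, sf_cpd=sf_cpd)
        for th in STRAIGHT_ORIENTATIONS
    }


def curved_specs(ratios, orientations=CURVE_ORIENTS,
                 sf_cpd: float = 1.0) -> dict[str, StimulusSpec]:
    return {
        f"c{ratio:g}_{orient}": StimulusSpec("curved_grating", float(ratio),
                                             orient, sf_cpd=sf_cpd)
        for orient in orientations for ratio in ratios
    }


def curvature_battery(ratios=(5.0,), orientations=CURVE_ORIENTS,
                      include_blank: bool = True) -> dict[str, StimulusSpec]:
    """Curved gratings × orientations plus the four straights (and a blank)."""
    conds = {}
    conds.update(curved_specs(ratios, orientations))
    conds.update(straight_specs())
    if include_blank:
        conds["blank"] = StimulusSpec("blank")
    return conds


# --------------------------------------------------------------------------- #
# pipeline conveniences
# --------------------------------------------------------------------------- #

def trial_responses_by_condition(session: ImagingSession) -> dict[str, np.ndarray]:
    """Per-condition (n_trials, rows, cols) scalar trial-response maps."""
    return {cid: trial_response(session.stack(cid))
            for cid in session.condition_ids}


def average_groups(responses: dict[str, np.ndarray], ids) -> np.ndarray:
    """Per-trial average of several conditions' trial responses (paired
    within blocks)."""
    return np.mean([responses[i] for i in ids], axis=0)


def curvature_vs_straight_maps(responses: dict[str, np.ndarray],
                               curved_ids, straight_ids):
    """The curvature map: average of curved vs. average of straight gratings."""
    return difference_statistic_map(
        average_groups(responses, curved_ids),
        average_groups(responses, straight_ids),
        contrast=(tuple(curved_ids), tuple(straight_ids)),
    )


def single_condition_maps(responses: dict[str, np.ndarray], cond_ids,
                          straight_ids, **kw) -> dict[str, SingleConditionResult]:
    straights = [responses[i] for i in straight_ids]
    return {cid: single_condition_map(responses[cid], straights,
                                      contrast=(cid, tuple(straight_ids)), **kw)
            for cid in cond_ids}


# --------------------------------------------------------------------------- #
# scenarios
# --------------------------------------------------------------------------- #

def null_scenario(seed: int, shape=(128, 128), n_trials: int = 30):
    """No planted structure: acquisition noise only."""
    params = CortexParams(shape=shape)
    model = make_model_with_retry(params, seed=seed)
    conds = curvature_battery(ratios=(5.0,), include_blank=False)
    session = simulate_session(model, conds, n_trials=n_trials,
                               noise=NoiseSpec(), seed=seed + 1)
    return model, session


def domain_recovery_scenario(seed: int, shape=(128, 128), n_trials: int = 30,
                             n_domains: int = 8):
    """Planted 0.2–0.5 mm curvature domains at exactly 0.02 % amplitude."""
    params = CortexParams(
        shape=shape,
        n_curvature_domains=n_domains,
        curvature_ratios=(5.0,),
        domain_radius_mm=(0.1, 0.25),
        amplitude_range=(2e-4, 2e-4),
    )
    model = make_model_with_retry(params, seed=seed)
    conds = curvature_battery(ratios=(5.0,))
    session = simulate_session(model, conds, n_trials=n_trials,
                               noise=NoiseSpec(), seed=seed + 1)
    return model, session


DEGREE_SERIES = (2.0, 3.0, 4.0, 5.0, 7.0, 10.0)


def degree_map_scenario(seed: int, shape=(128, 128), n_trials: int = 30,
                        ratios=DEGREE_SERIES):
    """Paired up/down degree progressions with broad degree tuning, plus
    standalone straight domains: the graded similarity-vs-degree structure."""
    params = CortexParams(
        shape=shape,
        n_progressions=2,
        progression_ratios=tuple(ratios),
        progression_spacing_mm=0.2,
        progression_paired=True,
        progression_phi_deg=90.0,   # chains carry up/down subdomain twins
        pair_overlap_iou=0.3,
        n_straight_domains=4,
        domain_radius_mm=(0.16, 0.2),
        degree_sigma=1.0,
        min_separation_mm=0.45,
    )
    model = make_model_with_retry(params, seed=seed)
    conds = {}
    conds.update(curved_specs(ratios, ("up", "down")))
    conds.update(straight_specs())
    conds["blank"] = StimulusSpec("blank")
    session = simulate_session(model, conds, n_trials=n_trials,
                               noise=NoiseSpec(), seed=seed + 1)
    return model, session


def orientation_pair_scenario(seed: int, shape=(128, 128), n_trials: int = 30,
                              n_pairs: int = 3, planted_iou: float = 0.2):
    """Opposing-orientation (up/down) subdomain pairs at a planted IoU."""
    params = CortexParams(
        shape=shape,
        n_orientation_pairs=n_pairs,
        pair_overlap_iou=planted_iou,
        pair_phi_deg=90.0,          # up/down pairs
        curvature_ratios=(5.0,),
        domain_radius_mm=(0.13, 0.18),
        amplitude_range=(2e-4, 2e-4),
        curvature_response_floor=0.05,  # sharp complementarity
    )
    model = make_model_with_retry(params, seed=seed)
    conds = curvature_battery(ratios=(5.0,), orientations=("up", "down"))
    session = simulate_session(model, conds, n_trials=n_trials,
                               noise=NoiseSpec(), seed=seed + 1)
    return model, session


PROGRESSION_RATIOS = (1.0, 2.0, 4.0, 5.0, 7.0, 10.0)


def progression_scenario(seed: int, shape=(128, 128), n_trials: int = 30,
                         n_progressions: int = 2,
                         jitter_mm: float = 0.05):
    """Straight→curved chains: 0.2 mm spacing over ratios 1–10, centroid
    jitter SD 0.05 mm, narrow degree tuning, a shared "up" orientation.

    Chains are kept farther apart than their own length so that the
    nearest-domain rule cannot capture a neighboring chain; a study of many
    progressions aggregates records over several simulated sessions."""
    params = CortexParams(
        shape=shape,
        n_progressions=n_progressions,
        progression_ratios=PROGRESSION_RATIOS,
        progression_spacing_mm=0.2,
        progression_jitter_mm=jitter_mm,
        progression_phi_deg=90.0,   # all chains point "up"
        progression_theta_deg=0.0,
        domain_radius_mm=(0.11, 0.13),
        degree_sigma=0.15,
        curvature_response_floor=0.05,
        min_separation_mm=1.3,
        orientation_band_fraction=0.7,
    )
    model = make_model_with_retry(params, seed=seed)
    conds = {}
    conds.update(curved_specs(PROGRESSION_RATIOS, ("up",)))
    conds.update(straight_specs())
    session = simulate_session(model, conds, n_trials=n_trials,
                               noise=NoiseSpec(), seed=seed + 1)
    return model, session
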