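"""Ground-truth generator and imaging forward model."""

import numpy as np
import pytest

from curvmap.preprocess import trial_response
from curvmap.stimuli import StimulusSpec
from curvmap.synth import (CortexParams, NoiseSpec, PlacementError,
                           frame_onset_times, hemodynamic_kernel,
                           make_cortical_model, pair_separation_for_iou,
                           simulate_session, tuning_response,
                           tuning_response_map)


def brute_force_winding_count(angle):
    """Loop-based plaquette winding oracle, independent of the detector."""
    def wrap(d):
        m = d % 180.0
        return m - 180.0 if m > 90.0 else m

    count = 0
    h, w = angle.shape
    for r in range(h - 1):
        for c in range(w - 1):
            loop = [angle[r, c], angle[r, c + 1], angle[r + 1, c + 1],
                    angle[r + 1, c], angle[r, c]]
            total = sum(wrap(b - a) for a, b in zip(loop, loop[1:]))
            if abs(total) > 90:
                count += 1
    return count


class TestModelGeneration:
    def test_determinism(self):
        p = CortexParams(shape=(64, 64), n_curvature_domains=2)
        m1 = make_cortical_model(p, seed=3)
        m2 = make_cortical_model(p, seed=3)
        assert np.array_equal(m1.orientation_angle_map, m2.orientation_angle_map)
        assert np.array_equal(m1.amplitude_map, m2.amplitude_map)
        for a, b in zip(m1.domains, m2.domains):
            assert a.center_px == b.center_px and a.ratio == b.ratio

    def test_pinwheel_ground_truth_matches_winding_oracle(self):
        m = make_cortical_model(CortexParams(shape=(64, 64)), seed=5)
        assert len(m.pinwheel_centers) == \
            brute_force_winding_count(m.orientation_angle_map)

    def test_progression_spacing_by_construction(self):
        p = CortexParams(shape=(128, 128), n_progressions=1,
                         progression_ratios=(1, 2, 4, 5, 7, 10),
                         progression_spacing_mm=0.2,
                         domain_radius_mm=(0.12, 0.12))
        m = make_cortical_model(p, seed=2)
        prog = m.planted_progressions[0]
        cents = np.array([prog.straight_centroid_mm] + prog.centroids_mm)
        gaps = np.linalg.norm(np.diff(cents, axis=0), axis=1)
        assert np.allclose(gaps, 0.2, atol=1e-9)

    def test_curvature_domains_inside_orientation_band(self):
        p = CortexParams(shape=(128, 128), n_curvature_domains=4)
        m = make_cortical_model(p, seed=8)
        assert not (m.curvature_domain_mask & ~m.band_map).any()

    def test_amplitude_range_default(self):
        m = make_cortical_model(CortexParams(shape=(64, 64)), seed=1)
        assert m.amplitude_map.min() >= 1e-4 and m.amplitude_map.max() <= 3e-4

    def test_infeasible_placement_raises(self):
        p = CortexParams(shape=(64, 64), n_curvature_domains=50,
                         domain_radius_mm=(0.3, 0.3), min_separation_mm=1.0)
        with pytest.raises(PlacementError):
            make_cortical_model(p, seed=0)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            make_cortical_model(CortexParams(shape=(32, 32)), seed=0)

    def test_pair_separation_solves_iou(self):
        r = 6.0
        for iou in (0.1, 0.2, 0.35):
            d = pair_separation_for_iou(r, iou)
            # numeric IoU of two rasterized disks
            rr, cc = np.mgrid[:64, :64]
            a = (rr - 32) ** 2 + (cc - 28) ** 2 <= r**2
            b = (rr - 32) ** 2 + (cc - 28 - d) ** 2 <= r**2
            got = (a & b).sum() / (a | b).sum()
            assert got == pytest.approx(iou, abs=0.05)


class TestTuning:
    def test_peak_response_equals_amplitude(self, small_model):
        dom = [d for d in small_model.domains if d.kind == "curvature"][0]
        px = tuple(int(round(v)) for v in dom.center_px)
        orient = {90.0: "up", 270.0: "down", 0.0: "right", 180.0: "left"}[dom.phi_deg]
        spec = StimulusSpec("curved_grating", dom.ratio, orient)
        resp = tuning_response(small_model, px, spec)
        assert resp == pytest.approx(small_model.amplitude_map[px], rel=1e-12)

    def test_blank_and_chromatic_gates(self, small_model):
        blank = tuning_response_map(small_model, StimulusSpec("blank"))
        assert not blank.any()
        chrom = tuning_response_map(
            small_model,
            StimulusSpec("straight_grating", 0.0, 45.0, chromatic=True))
        # chromatic stimuli drive the color band only
        assert not chrom[small_model.band_map].any()
        assert (chrom[~small_model.band_map] > 0).all()

    def test_degree_tuning_monotone_toward_preference(self, small_model):
        dom = [d for d in small_model.domains if d.kind == "curvature"][0]
        px = tuple(int(round(v)) for v in dom.center_px)
        orient = {90.0: "up", 270.0: "down", 0.0: "right", 180.0: "left"}[dom.phi_deg]
        # preferred ratio is 5; responses over 1..5 increase monotonically
        resps = [tuning_response(small_model, px,
                                 StimulusSpec("curved_grating", r, orient))
                 for r in (1, 2, 4, 5)]
        assert all(b > a for a, b in zip(resps, resps[1:]))

    def test_pixel_out_of_grid(self, small_model):
        with pytest.raises(IndexError):
            tuning_response(small_model, (999, 0), StimulusSpec("blank"))


class TestForwardModel:
    def test_kernel_unit_peak_between_2_and_3_s(self):
        t = np.linspace(0, 6, 2401)
        k = hemodynamic_kernel(t)
        assert k.max() == pytest.approx(1.0, abs=1e-6)
        assert 2.0 <= t[np.argmax(k)] <= 3.0
        assert np.all(k[t <= 0] == 0)

    def test_prestim_frames_carry_no_signal(self):
        t = frame_onset_times(20, 4.0, 2)
        k = hemodynamic_kernel(t)
        assert np.all(k[:3] == 0)  # 2 pre-stim frames + onset frame

    def test_noiseless_trial_response_closed_form(self, small_model,
                                                  noiseless_session):
        """trial response = −resp·k̄ with k̄ the kernel mean over frames 8–16."""
        sess = noiseless_session
        t_rel = frame_onset_times(sess.n_frames, sess.frame_rate_hz,
                                  sess.n_prestim_frames)
        kbar = hemodynamic_kernel(t_rel)[7:16].mean()
        resp = tuning_response_map(small_model, sess.condition_table["c5_up"])
        got = trial_response(sess.stack("c5_up"))[0]
        assert np.abs(got - (-resp * kbar)).max() < 1e-12

    def test_amplitude_linearity(self, small_model, noiseless_session):
        import copy

        m2 = copy.deepcopy(small_model)
        m2.amplitude_map = 2.0 * m2.amplitude_map
        s2 = simulate_session(
            m2, noiseless_session.condition_table, n_trials=1,
            noise=NoiseSpec(0.0, 0.0, 10.0, 0.0), seed=7, dtype=np.float64)
        r1 = trial_response(noiseless_session.stack("c5_up"))[0]
        r2 = trial_response(s2.stack("c5_up"))[0]
        assert np.abs(r2 - 2 * r1).max() < 1e-10

    def test_same_seed_bit_identical(self, small_model, tiny_conditions):
        kw = dict(n_trials=2, noise=NoiseSpec(seed=3), seed=11)
        s1 = simulate_session(small_model, tiny_conditions, **kw)
        s2 = simulate_session(small_model, tiny_conditions, **kw)
        assert np.array_equal(s1.data, s2.data)

    def test_activation_darkens(self, small_model, noiseless_session):
        dom = [d for d in small_model.domains if d.kind == "curvature"][0]
        mask = dom.mask(small_model.shape)
        stack = noiseless_session.stack("c5_up")[0]
        assert stack[12][mask].mean() < stack[0][mask].mean()

    def test_frame_count_invariant(self, small_model, tiny_conditions):
        s = simulate_session(small_model, tiny_conditions, n_trials=1,
                             stim_duration_s=3.5, seed=0)
        assert s.n_frames == 2 + round(3.5 * 4)
        assert (s.data > 0).all()
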