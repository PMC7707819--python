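"""Stimulus rendering: ellipse geometry, symmetries, drift, scrambling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curvmap import stimuli as stim
from curvmap.stimuli import (StimulusSpec, apply_block_permutation,
                             curvature_index, curved_grating_image,
                             render_flashed_line, scramble_permutation,
                             scramble_stimulus, straight_grating_image)

# odd grid => a pixel sits exactly on the central axis x = 0
ODD_PITCH = 4.0 / 401


@pytest.mark.parametrize("a, b, expected", [(2, 1, 2), (3, 3, 1), (5, 1, 5)])
def test_curvature_index(a, b, expected):
    assert curvature_index(a, b) == expected


@pytest.mark.parametrize("a, b", [(0, 1), (1, 0), (-2, 1)])
def test_curvature_index_invalid(a, b):
    with pytest.raises(ValueError):
        curvature_index(a, b)


def test_central_axis_profile_independent_of_ratio():
    """The profile on the vertical axis is the same sinusoid for any ratio."""
    p2 = curved_grating_image(2, "up", 1.0, 4.0, ODD_PITCH)[:, 200]
    p5 = curved_grating_image(5, "up", 1.0, 4.0, ODD_PITCH)[:, 200]
    assert np.abs(p2 - p5).max() < 1e-9


def test_flank_spatial_frequency_rises_with_ratio():
    """Along a horizontal cut, the local SF (mid-luminance crossings per
    degree) grows toward the stimulus edge, faster for sharper curvature."""
    def crossings(ratio, col_lo, col_hi, row=120):
        img = curved_grating_image(ratio, "up", 1.0, 4.0, 0.01)
        cut = img[row, col_lo:col_hi]
        return np.diff(np.signbit(cut - 0.5)).sum()

    center2 = crossings(2, 180, 220)
    flank2 = crossings(2, 360, 400)
    flank5 = crossings(5, 360, 400)
    assert flank2 > center2          # SF rises toward the flank
    assert flank5 > flank2           # more steeply for higher curvature


def test_mirror_and_rotation_closure():
    up = curved_grating_image(5, "up", 1.0, 4.0, 0.02)
    down = curved_grating_image(5, "down", 1.0, 4.0, 0.02)
    left = curved_grating_image(5, "left", 1.0, 4.0, 0.02)
    right = curved_grating_image(5, "right", 1.0, 4.0, 0.02)
    assert np.array_equal(np.flipud(up), down)
    assert np.array_equal(up.T, left)
    assert np.array_equal(np.fliplr(up.T), right)


def test_zero_ratio_equals_straight_grating():
    c = curved_grating_image(0.0, "up", 1.0, 4.0, 0.02, t=0.3, phase=0.7)
    s = straight_grating_image(0.0, 1.0, 4.0, 0.02, t=0.3, phase=0.7)
    assert np.array_equal(c, s)


def test_straight_orientation_180_periodic():
    a = straight_grating_image(30.0, 1.0, 4.0, 0.02)
    b = straight_grating_image(210.0, 1.0, 4.0, 0.02)
    assert np.array_equal(a, b)


def test_mean_luminance_half():
    img = straight_grating_image(0.0, 1.0, 4.0, 0.01)
    assert img.mean() == pytest.approx(0.5, abs=2e-3)


@given(ratio=st.floats(0.5, 10), t=st.floats(0, 3),
       orient=st.sampled_from(["up", "down", "left", "right"]))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_luminance_in_unit_interval(ratio, t, orient):
    img = curved_grating_image(ratio, orient, 1.0, 4.0, 0.05, t=t)
    assert img.min() >= 0.0 and img.max() <= 1.0


def test_drift_periodicity():
    sf, speed = 1.0, 2.0
    period = 1.0 / (sf * speed)
    a = curved_grating_image(5, "up", sf, 4.0, 0.02, t=0.1, drift_speed_deg_s=speed)
    b = curved_grating_image(5, "up", sf, 4.0, 0.02, t=0.1 + period,
                             drift_speed_deg_s=speed)
    assert np.allclose(a, b, atol=1e-9)


def test_flashed_line_off_is_black_and_straight_line_is_thin():
    spec = StimulusSpec("straight_line", 0.0, 0.0)
    off = render_flashed_line(spec, on=False, pixel_pitch_deg=0.02)
    assert not off.luminance.any()
    on = render_flashed_line(spec, on=True, pixel_pitch_deg=0.02)
    rows = np.nonzero(on.luminance.any(axis=1))[0]
    n = on.luminance.shape[0]
    assert rows.size >= 1 and np.abs(rows - (n - 1) / 2).max() <= 2


def test_curved_line_arc_length_grows_with_ratio():
    """Over the columns where neither curve is cropped by the aperture, the
    midline arc (polyline through per-column lit-pixel centers) of the
    sharper curve is longer."""
    def midline(ratio):
        spec = StimulusSpec("curved_line", ratio, "up")
        img = render_flashed_line(spec, pixel_pitch_deg=0.01,
                                  line_width_deg=0.05).luminance
        n = img.shape[0]
        out = {}
        for c in range(img.shape[1]):
            r = np.nonzero(img[:, c])[0]
            if r.size and r.max() < n - 1:     # not cropped at the edge
                out[c] = r.mean()
        return out

    m2, m5 = midline(2), midline(5)
    common = sorted(set(m2) & set(m5))
    arc2 = np.hypot(np.diff([m2[c] for c in common]), 1.0).sum()
    arc5 = np.hypot(np.diff([m5[c] for c in common]), 1.0).sum()
    assert arc5 > arc2 > len(common) - 1  # both longer than a straight chord


def test_curved_line_vertex_at_center():
    spec = StimulusSpec("curved_line", 5.0, "up")
    img = render_flashed_line(spec, pixel_pitch_deg=ODD_PITCH).luminance
    c = img.shape[0] // 2
    assert img[c, c] == 1.0


class TestScramble:
    def test_identity_permutation(self):
        img = curved_grating_image(5, "up", 1.0, 4.0, 0.05)
        out = apply_block_permutation(img, np.arange(64))
        assert np.array_equal(out, img[:80, :80])  # 80 = largest 8-divisible

    def test_histogram_preserved_bit_exactly(self):
        img = curved_grating_image(5, "up", 1.0, 4.0, 0.05)[:80, :80]
        perm = scramble_permutation(64, seed=3)
        out = apply_block_permutation(img, perm)
        assert np.array_equal(np.sort(out.ravel()), np.sort(img.ravel()))

    def test_inverse_restores_input(self):
        img = curved_grating_image(5, "up", 1.0, 4.0, 0.05)[:80, :80]
        perm = scramble_permutation(64, seed=9)
        inv = np.argsort(perm)
        assert np.array_equal(
            apply_block_permutation(apply_block_permutation(img, perm), inv), img)

    def test_64_subunits_is_8x8(self):
        perm = scramble_permutation(64, seed=0)
        assert perm.size == 64
        with pytest.raises(ValueError):
            scramble_permutation(60, seed=0)

    def test_scramble_frame_roundtrip_shape(self):
        spec = StimulusSpec("curved_grating", 5.0, "up")
        frame = stim.render_curved_grating(spec, pixel_pitch_deg=0.05)
        out = scramble_stimulus(frame, 64, seed=1)
        assert out.luminance.shape == (80, 80)


class TestSpecValidation:
    def test_curved_requires_positive_ratio(self):
        with pytest.raises(ValueError):
            StimulusSpec("curved_grating", 0.0, "up")

    def test_straight_requires_zero_ratio(self):
        with pytest.raises(ValueError):
            StimulusSpec("straight_grating", 2.0, 0.0)

    def test_subunits_perfect_square(self):
        with pytest.raises(ValueError):
            StimulusSpec("curved_grating", 5.0, "up", n_scramble_subunits=63)

    def test_roundtrip_dict(self):
        spec = StimulusSpec("curved_grating", 5.0, "left", sf_cpd=0.5)
        assert StimulusSpec.from_dict(spec.to_dict()) == spec
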