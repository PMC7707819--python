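"""dR/R normalization, trial responses, t-statistic maps, spatial filtering."""

import numpy as np
import pytest
from scipy import stats

from curvmap.preprocess import (difference_statistic_map, filter_map,
                                frame_drr, single_condition_map,
                                trial_response)


def brute_force_drr(stack, n_base):
    out = np.empty_like(stack, dtype=float)
    f, h, w = stack.shape
    for r in range(h):
        for c in range(w):
            f0 = stack[:n_base, r, c].mean()
            for k in range(f):
                out[k, r, c] = (stack[k, r, c] - f0) / f0
    return out


def brute_force_trial_response(stack):
    f, h, w = stack.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            base = stack[0:3, r, c].mean()
            resp = stack[7:16, r, c].mean()
            out[r, c] = (resp - base) / base
    return out


def brute_force_paired_t(a, b):
    n, h, w = a.shape
    t = np.empty((h, w))
    p = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            d = a[:, r, c] - b[:, r, c]
            s = d.std(ddof=1)
            t[r, c] = d.mean() * np.sqrt(n) / s
            p[r, c] = 2 * stats.t.sf(abs(t[r, c]), n - 1)
    return t, p


class TestFrameDrr:
    def test_constant_stack_is_zero(self):
        stack = np.full((6, 4, 4), 100.0)
        assert np.array_equal(frame_drr(stack), np.zeros_like(stack))

    def test_one_percent_drop(self):
        stack = np.full((5, 3, 3), 100.0)
        stack[3:] = 99.0
        drr = frame_drr(stack)
        assert np.allclose(drr[3:], -0.01)

    def test_matches_brute_force(self, rng):
        stack = rng.uniform(50, 150, size=(4, 3, 3))
        assert np.allclose(frame_drr(stack), brute_force_drr(stack, 2),
                           atol=1e-12)

    def test_scale_invariance(self, rng):
        stack = rng.uniform(50, 150, size=(6, 4, 4))
        assert np.allclose(frame_drr(stack), frame_drr(3.7 * stack), atol=1e-12)

    def test_nonpositive_baseline_names_pixel(self):
        stack = np.full((4, 2, 2), 10.0)
        stack[:2, 1, 0] = 0.0
        with pytest.raises(ZeroDivisionError, match=r"row=1, col=0"):
            frame_drr(stack)


class TestTrialResponse:
    def test_frames_8_16_vs_1_3(self):
        stack = np.full((16, 3, 3), 100.0)
        stack[7:16] = 99.0
        stack[3:7] = 55.0  # irrelevant frames
        assert np.allclose(trial_response(stack), -0.01)

    def test_matches_brute_force(self, rng):
        stack = rng.uniform(50, 150, size=(20, 4, 4))
        assert np.allclose(trial_response(stack),
                           brute_force_trial_response(stack), atol=1e-12)

    def test_short_stack_raises(self):
        with pytest.raises(ValueError, match="frames"):
            trial_response(np.ones((15, 2, 2)))

    def test_trial_axis_broadcast(self, rng):
        stacks = rng.uniform(50, 150, size=(5, 20, 3, 3))
        out = trial_response(stacks)
        assert out.shape == (5, 3, 3)
        assert np.allclose(out[2], trial_response(stacks[2]))


class TestDifferenceStatisticMap:
    def test_identical_groups(self, rng):
        a = rng.normal(size=(5, 4, 4))
        t, p = difference_statistic_map(a, a.copy())
        assert np.array_equal(t.values, np.zeros((4, 4)))
        assert np.array_equal(p.values, np.ones((4, 4)))

    def test_swap_antisymmetry_exact(self, rng):
        a = rng.normal(size=(6, 5, 5))
        b = rng.normal(size=(6, 5, 5))
        t_ab, _ = difference_statistic_map(a, b)
        t_ba, _ = difference_statistic_map(b, a)
        assert np.array_equal(t_ab.values, -t_ba.values)

    def test_paired_t_oracle(self, rng):
        a = rng.normal(size=(5, 8, 8))
        b = rng.normal(size=(5, 8, 8))
        t, p = difference_statistic_map(a, b)
        t_ref, p_ref = brute_force_paired_t(a, b)
        assert np.abs(t.values - t_ref).max() < 1e-10
        assert np.abs(p.values - p_ref).max() < 1e-10

    def test_scipy_cross_check(self, rng):
        a = rng.normal(size=(7, 3, 3))
        b = rng.normal(size=(7, 3, 3))
        t, p = difference_statistic_map(a, b, paired=True)
        res = stats.ttest_rel(a, b, axis=0)
        assert np.allclose(t.values, res.statistic)
        assert np.allclose(p.values, res.pvalue)
        t, p = difference_statistic_map(a, b, paired=False)
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        assert np.allclose(t.values, res.statistic)
        assert np.allclose(p.values, res.pvalue)

    def test_zero_variance_sentinel(self):
        a = np.ones((4, 2, 2))
        b = np.zeros((4, 2, 2))
        t, p = difference_statistic_map(a, b)
        assert np.all(np.isinf(t.values)) and np.all(t.values > 0)
        assert np.array_equal(p.values, np.zeros((2, 2)))

    def test_literal_n_scaling_is_monotone_transform(self, rng):
        a = rng.normal(size=(6, 4, 4))
        b = rng.normal(size=(6, 4, 4))
        t1, p1 = difference_statistic_map(a, b, scaling="sqrt_n")
        t2, p2 = difference_statistic_map(a, b, scaling="n")
        assert np.allclose(t2.values, t1.values * np.sqrt(6))
        assert np.array_equal(p1.values, p2.values)

    def test_paired_requires_equal_n(self, rng):
        with pytest.raises(ValueError):
            difference_statistic_map(rng.normal(size=(4, 2, 2)),
                                     rng.normal(size=(5, 2, 2)), paired=True)


class TestFilterMap:
    def test_constant_map_zeroed(self):
        out = filter_map(np.full((64, 64), 3.5), 10, 40)
        assert np.abs(out).max() < 1e-10

    def test_linear_ramp_suppressed(self):
        ramp = np.linspace(-1, 1, 128)[None, :] * np.ones((128, 1))
        out = filter_map(ramp, 10, 120)
        interior = out[20:-20, 20:-20]
        assert np.abs(interior).max() < 0.1 * np.abs(ramp).max()

    def test_blob_retained(self):
        """A 0.4 mm blob at the acquisition scale (8 µm/px → FWHM 50 px)
        passes the 10/120 px filter pair with most of its peak.

        Closed-form response: Gaussian-smoothing attenuates the peak by
        σ_b²/(σ_b² + σ_s²) ≈ 0.96 and the 120 px circular mean removes
        2σ_b²/R² ≈ 0.25 of it, leaving ≈ 0.72 of the original peak.
        """
        yy, xx = np.mgrid[:256, :256] - 128.0
        sigma_b = 50 / 2.355
        blob = np.exp(-(yy**2 + xx**2) / (2 * sigma_b**2))
        out = filter_map(blob, 10, 120)
        sigma_s = 10 / 2.355
        expected = sigma_b**2 / (sigma_b**2 + sigma_s**2) \
            - 2 * sigma_b**2 / 60.0**2
        assert out[128, 128] == pytest.approx(expected, abs=0.03)
        assert out[128, 128] > 0.65

    def test_nan_preserved(self):
        v = np.random.default_rng(0).normal(size=(32, 32))
        v[:5, :5] = np.nan
        out = filter_map(v, 4, 16)
        assert np.isnan(out[:5, :5]).all()
        assert np.isfinite(out[10:, 10:]).all()

    def test_bad_diameters(self):
        with pytest.raises(ValueError):
            filter_map(np.zeros((16, 16)), 10, 10)


class TestSingleConditionMap:
    def test_condition_equal_to_straight_average(self, rng):
        straights = {th: rng.normal(size=(5, 8, 8)) for th in (0, 45, 90, 135)}
        cond = np.mean(list(straights.values()), axis=0)
        res = single_condition_map(cond, straights, lowfreq_diameter_px=6,
                                   smooth_diameter_px=2)
        assert np.array_equal(res.t.values, np.zeros((8, 8)))

    def test_empty_straight_set(self, rng):
        with pytest.raises(ValueError):
            single_condition_map(rng.normal(size=(5, 4, 4)), [])
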