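"""Domain detection, morphometrics, small-patch exclusion, overlap."""

import numpy as np
import pytest
from scipy import stats

from curvmap.domains import (DomainSet, anova_tukey_gate, detect_domains,
                             domain_morphometry, filter_small_patches,
                             overlap_percentage)


def disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def brute_force_moment_radius(mask):
    """Second-moment ellipse semi-axes from raw pixel moments."""
    rows, cols = np.nonzero(mask)
    r0, c0 = rows.mean(), cols.mean()
    mrr = ((rows - r0) ** 2).mean()
    mcc = ((cols - c0) ** 2).mean()
    mrc = ((rows - r0) * (cols - c0)).mean()
    lam = np.linalg.eigvalsh([[mrr, mrc], [mrc, mcc]])
    # ellipse with the same normalized second moments: semi-axis = 2·sqrt(λ)
    return (2 * np.sqrt(lam[0]) + 2 * np.sqrt(lam[1])) / 2


class TestDetect:
    def test_all_insignificant_gives_empty_set(self):
        t = -np.ones((16, 16))
        p = np.ones((16, 16))
        ds = detect_domains(t, p, alpha=0.01, pixel_size_mm=0.02)
        assert len(ds) == 0 and not ds.mask().any()

    def test_planted_disk_single_label(self):
        mask = disk_mask((32, 32), (16, 16), 5)
        t = np.where(mask, -5.0, 0.1)
        p = np.where(mask, 1e-5, 0.9)
        ds = detect_domains(t, p, pixel_size_mm=0.02)
        assert len(ds) == 1
        assert np.array_equal(ds.mask(), mask)

    def test_sign_selects_direction(self):
        mask = disk_mask((32, 32), (16, 16), 5)
        t = np.where(mask, 5.0, 0.0)  # positive activation
        p = np.where(mask, 1e-5, 0.9)
        assert len(detect_domains(t, p, sign="negative", pixel_size_mm=0.02)) == 0
        assert len(detect_domains(t, p, sign="positive", pixel_size_mm=0.02)) == 1

    def test_connectivity_flag_on_diagonal_touch(self):
        t = np.zeros((8, 8))
        p = np.ones((8, 8))
        for r, c in [(2, 2), (3, 3)]:  # touch only diagonally
            t[r, c] = -4
            p[r, c] = 1e-4
        assert len(detect_domains(t, p, connectivity=2, pixel_size_mm=1)) == 1
        assert len(detect_domains(t, p, connectivity=1, pixel_size_mm=1)) == 2

    def test_label_pixel_counts_consistent(self, rng):
        t = rng.normal(size=(64, 64))
        p = rng.uniform(size=(64, 64))
        ds = detect_domains(t, p, alpha=0.2, pixel_size_mm=0.01)
        assert ds.domains["n_pixels"].sum() == (ds.label_image > 0).sum()


class TestMorphometry:
    def test_disk_diameter_and_area(self):
        px = 0.01
        mask = disk_mask((128, 128), (64, 64), 20)  # diameter 0.4 mm
        area, diam, centroid = domain_morphometry(mask, px)
        assert diam == pytest.approx(0.4, rel=0.03)
        assert area == pytest.approx(np.pi * 0.2**2, rel=0.06)
        assert centroid == pytest.approx((0.64, 0.64), abs=1e-9)

    def test_rectangle_matches_brute_force_moments(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:40, 10:50]  = True  # 20 x 40 rectangle
        _, diam, _ = domain_morphometry(mask, 1.0)
        assert diam / 2 == pytest.approx(brute_force_moment_radius(mask), rel=1e-6)

    def test_translation_equivariance(self):
        m1 = disk_mask((64, 64), (20, 20), 6)
        m2 = disk_mask((64, 64), (29, 35), 6)
        _, _, c1 = domain_morphometry(m1, 0.05)
        _, _, c2 = domain_morphometry(m2, 0.05)
        assert np.allclose(np.subtract(c2, c1), (9 * 0.05, 15 * 0.05))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            domain_morphometry(np.zeros((8, 8), dtype=bool), 0.01)


class TestSmallPatchFilter:
    def test_large_domains_unchanged(self):
        mask = disk_mask((64, 64), (32, 32), 10)  # 0.3 mm at 15 µm/px
        t = np.where(mask, -4.0, 0.0)
        p = np.where(mask, 1e-4, 1.0)
        ds = detect_domains(t, p, pixel_size_mm=0.015)
        out = filter_small_patches(ds, 0.2)
        assert len(out) == len(ds) == 1

    def test_two_pixel_patch_removed(self):
        t = np.zeros((16, 16))
        p = np.ones((16, 16))
        t[5, 5:7] = -4
        p[5, 5:7] = 1e-4
        ds = detect_domains(t, p, pixel_size_mm=0.008)
        assert len(filter_small_patches(ds, 0.2)) == 0

    def test_mixed_set_matches_brute_force_and_relabels(self, rng):
        t = np.zeros((128, 128))
        p = np.ones((128, 128))
        radii = [3, 8, 12, 2, 15]
        centers = [(15, 15), (40, 40), (70, 70), (100, 20), (100, 100)]
        for (r0, c0), rad in zip(centers, radii):
            m = disk_mask((128, 128), (r0, c0), rad)
            t[m] = -5
            p[m] = 1e-5
        ds = detect_domains(t, p, pixel_size_mm=0.01)
        out = filter_small_patches(ds, 0.2)
        expected = sum(
            ds.domains["equivalent_diameter_mm"] >= 0.2)
        assert len(out) == expected
        assert list(out.domains["id"]) == list(range(1, len(out) + 1))
        assert set(np.unique(out.label_image)) == set(range(len(out) + 1))


class TestOverlap:
    def test_identical_masks(self):
        m = disk_mask((32, 32), (16, 16), 5)
        assert overlap_percentage(m, m) == 100.0

    def test_disjoint_masks(self):
        a = disk_mask((32, 32), (8, 8), 4)
        b = disk_mask((32, 32), (24, 24), 4)
        assert overlap_percentage(a, b) == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert overlap_percentage(a, b) == pytest.approx(100 * 50 / 150)

    def test_both_empty_warns_zero(self):
        z = np.zeros((8, 8), dtype=bool)
        with pytest.warns(UserWarning):
            assert overlap_percentage(z, z) == 0.0


class TestAnovaGate:
    def test_gate_matches_scipy_f_oneway(self, rng):
        pref = [rng.normal(-1, 1, size=(10, 6, 6)) for _ in range(2)]
        ref = [rng.normal(0, 1, size=(10, 6, 6)) for _ in range(2)]
        gate = anova_tukey_gate(pref, ref, alpha=0.05)
        f, p = stats.f_oneway(*(pref + ref), axis=0)
        # every gated pixel passed the ANOVA component
        assert not (gate & (p >= 0.05)).any()

    def test_strong_separation_passes_null_does_not(self, rng):
        pref = [np.full((8, 4, 4), -5.0) + rng.normal(0, 0.1, (8, 4, 4))]
        ref = [rng.normal(0, 0.1, size=(8, 4, 4)) for _ in range(2)]
        assert anova_tukey_gate(pref, ref).all()
        null = [rng.normal(0, 1, size=(8, 16, 16)) for _ in range(3)]
        frac = anova_tukey_gate(null[:1], null[1:]).mean()
        assert frac < 0.05
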