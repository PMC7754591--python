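"""Feature bank vs independent brute-force oracles plus structural
invariants (slice locality, monotonic invariance, fixed channel order)."""

import numpy as np
import pytest

import oracles
from handmuscle import (
    CHANNEL_CATALOG,
    ElbpConfig,
    GaborConfig,
    ScalarVolume,
    elbp,
    extract_features,
    gabor_bank,
    neighborhood_stats,
    sobel_gradient_magnitude,
)
from handmuscle.features import gabor_kernel


class TestNeighborhoodStats:
    def test_constant_image_gives_constant_mean_and_zero_sd(self):
        vol = ScalarVolume(np.full((3, 9, 9), 42.0, np.float32))
        data, names = neighborhood_stats(vol)
        for ch, name in zip(data, names):
            if name.startswith("mean"):
                np.testing.assert_allclose(ch, 42.0, atol=1e-9)
            else:
                np.testing.assert_allclose(ch, 0.0, atol=1e-4)

    def test_single_bright_voxel_mean_is_value_over_diamond_size(self):
        arr = np.zeros((1, 9, 9), np.float32)
        arr[0, 4, 4] = 10.0
        data, names = neighborhood_stats(ScalarVolume(arr), radii_2d=(1,), radii_3d=())
        mean_r1 = data[names.index("mean2d_r1")]
        # city-block ball of radius 1 has 5 voxels
        assert mean_r1[0, 4, 4] == pytest.approx(10.0 / 5)

    def test_ramp_center_matches_diamond_enumeration(self):
        ramp = np.add.outer(np.arange(7.0), np.arange(7.0))[None].astype(np.float32)
        data, names = neighborhood_stats(ScalarVolume(ramp), radii_2d=(2,), radii_3d=())
        mean_r2 = data[names.index("mean2d_r2")]
        vals = [ramp[0, 3 + dy, 3 + dx]
                for dy in range(-2, 3) for dx in range(-2, 3) if abs(dy) + abs(dx) <= 2]
        assert len(vals) == 13
        assert mean_r2[0, 3, 3] == pytest.approx(np.mean(vals))

    @pytest.mark.parametrize("r,three_d", [(1, False), (2, False), (4, True)])
    def test_oracle_equivalence_on_random_volumes(self, rng, r, three_d):
        vol = ScalarVolume(rng.normal(0, 1, (3, 9, 9)).astype(np.float32))
        data, names = neighborhood_stats(
            vol, radii_2d=() if three_d else (r,), radii_3d=(r,) if three_d else ()
        )
        tag = f"{'3d' if three_d else '2d'}_r{r}"
        mean_o, sd_o = oracles.neighborhood_mean_sd(vol.data.astype(float), r, three_d)
        np.testing.assert_allclose(data[names.index(f"mean{tag}")], mean_o, atol=1e-6)
        np.testing.assert_allclose(data[names.index(f"sd{tag}")], sd_o, atol=1e-6)


class TestSobel:
    def test_constant_image_has_zero_gradient(self):
        out = sobel_gradient_magnitude(ScalarVolume(np.full((2, 8, 8), 7.0, np.float32)))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_vertical_step_edge_peaks_on_edge_column(self):
        arr = np.zeros((1, 8, 8), np.float32)
        arr[:, :, 4:] = 100.0
        out = sobel_gradient_magnitude(ScalarVolume(arr))
        assert out[0, 4, 3] > 0 and out[0, 4, 4] > 0
        assert out[0, 4, 1] == pytest.approx(0.0, abs=1e-9)

    def test_oracle_equivalence_on_random_patch(self, rng):
        vol = ScalarVolume(rng.normal(0, 1, (2, 5, 5)).astype(np.float32))
        np.testing.assert_allclose(
            sobel_gradient_magnitude(vol),
            oracles.sobel_magnitude(vol.data.astype(float)),
            atol=1e-6,
        )


class TestElbp:
    def test_constant_image_gives_all_tie_codes(self):
        vol = ScalarVolume(np.full((2, 9, 9), 5.0, np.float32))
        data, names = elbp(vol, ElbpConfig(radius_outer=3, n_samples=8))
        for ch, name in zip(data, names):
            if name in ("elbp_rd", "elbp_ad"):
                np.testing.assert_allclose(ch, 0.0)

    def test_cone_gives_all_ones_radial_and_all_tie_angular_code(self):
        # radially symmetric cone peaked at the center voxel: inner samples
        # are brighter than outer ones at every angle. n = 4 keeps every
        # sample on a lattice axis where bilinear interpolation reproduces
        # the cone exactly, so the angular samples are true ties.
        n = 4
        yy, xx = np.mgrid[0:17, 0:17].astype(float)
        cone = (20.0 - np.hypot(yy - 8, xx - 8))[None].astype(np.float32)
        data, names = elbp(ScalarVolume(cone), ElbpConfig(radius_outer=3, n_samples=n))
        rd = data[names.index("elbp_rd")]
        ad = data[names.index("elbp_ad")]
        assert rd[0, 8, 8] == 2**n - 1
        assert ad[0, 8, 8] == 0.0

    def test_oracle_equivalence_on_random_patches(self, rng):
        vol = ScalarVolume(rng.normal(100, 25, (3, 9, 9)).astype(np.float32))
        cfg = ElbpConfig(radius_outer=3.0, n_samples=8)
        data, names = elbp(vol, cfg)
        ci_o, ni_o, rd_o, ad_o = oracles.elbp_codes(
            vol.data.astype(np.float64), cfg.radius_outer, cfg.n_samples
        )
        np.testing.assert_array_equal(data[names.index("elbp_ci")], ci_o)
        np.testing.assert_array_equal(data[names.index("elbp_ni")], ni_o)
        np.testing.assert_array_equal(data[names.index("elbp_rd")], rd_o)
        np.testing.assert_array_equal(data[names.index("elbp_ad")], ad_o)

    def test_difference_codes_invariant_to_strictly_monotonic_maps(self, rng):
        # with radius 2 and 4 samples every sample sits on the pixel
        # lattice, so no interpolation intervenes and the difference codes
        # are exactly invariant under any strictly increasing map.
        # (interpolated off-lattice samples commute only with affine maps,
        # covered by the test below.)
        data = rng.normal(100, 20, (2, 11, 11)).astype(np.float32)
        cfg = ElbpConfig(radius_outer=2.0, n_samples=4)
        base, names = elbp(ScalarVolume(data), cfg)
        mapped, _ = elbp(ScalarVolume(np.exp(data / 50.0).astype(np.float32)), cfg)
        for name in ("elbp_rd", "elbp_ad"):  # mean-referenced codes exempt
            i = names.index(name)
            np.testing.assert_array_equal(base[i], mapped[i])

    def test_all_channels_invariant_to_increasing_affine_maps(self, rng):
        data = rng.normal(100, 20, (2, 11, 11)).astype(np.float32)
        cfg = ElbpConfig(radius_outer=2.0, n_samples=8)
        base, names = elbp(ScalarVolume(data), cfg)
        mapped, _ = elbp(ScalarVolume(3.0 * data + 17.0), cfg)
        np.testing.assert_array_equal(base, mapped)


class TestGabor:
    def test_exactly_four_orientation_channels(self, rng):
        vol = ScalarVolume(rng.normal(0, 1, (2, 8, 8)).astype(np.float32))
        data, names = gabor_bank(vol, GaborConfig(kernel_size=7))
        assert data.shape[0] == 4
        assert names == ["gabor_0", "gabor_45", "gabor_90", "gabor_135"]

    def test_constant_image_response_equals_kernel_sum(self):
        cfg = GaborConfig(kernel_size=9, sigma=1.0, wavelength=1.0)
        vol = ScalarVolume(np.full((1, 15, 15), 3.0, np.float32), spacing=(1, 1, 1))
        data, _ = gabor_bank(vol, cfg)
        for i, ang in enumerate(cfg.orientations_deg):
            ksum = gabor_kernel(cfg, ang, (1.0, 1.0)).sum()
            assert data[i, 0, 7, 7] == pytest.approx(3.0 * ksum, rel=1e-6)

    def test_grating_selects_matching_orientation(self):
        # horizontal grating (varies along y) at the filter wavelength:
        # the 90-degree channel must dominate the 0-degree channel
        cfg = GaborConfig(kernel_size=9, sigma=2.0, wavelength=4.0)
        y = np.arange(32.0)
        grating = np.tile(np.cos(2 * np.pi * y / 4.0)[:, None], (1, 32))[None]
        vol = ScalarVolume(grating.astype(np.float32), spacing=(1, 1, 1))
        data, names = gabor_bank(vol, cfg)
        r90 = np.abs(data[names.index("gabor_90")][0, 12:20, 12:20]).mean()
        r0 = np.abs(data[names.index("gabor_0")][0, 12:20, 12:20]).mean()
        assert r90 > 10 * r0

    def test_oracle_equivalence_on_random_patch(self, rng):
        cfg = GaborConfig(kernel_size=7, sigma=1.2, wavelength=2.0)
        vol = ScalarVolume(rng.normal(0, 1, (2, 9, 9)).astype(np.float32), spacing=(0.5, 0.5, 3.0))
        data, _ = gabor_bank(vol, cfg)
        for i, ang in enumerate(cfg.orientations_deg):
            expected = oracles.gabor_response(
                vol.data.astype(float), 7, 1.2, 2.0, ang, spacing_xy=(0.5, 0.5)
            )
            np.testing.assert_allclose(data[i], expected, atol=1e-6)

    def test_even_kernel_size_rounded_up_to_odd(self):
        cfg = GaborConfig(kernel_size=8)
        assert cfg.kernel_size_odd == 9
        assert gabor_kernel(cfg, 0.0, (1.0, 1.0)).shape == (9, 9)


class TestExtractFeatures:
    def test_full_bank_has_21_finite_channels_in_catalog_order(self, rng):
        vol = ScalarVolume(rng.normal(100, 20, (3, 15, 15)).astype(np.float32))
        ft = extract_features(vol)
        assert ft.n_channels == 21
        assert ft.channels == CHANNEL_CATALOG
        assert sum(c.startswith("gabor") for c in ft.channels) == 4
        assert np.isfinite(ft.data).all()

    def test_extraction_is_deterministic(self, rng):
        vol = ScalarVolume(rng.normal(0, 1, (2, 10, 10)).astype(np.float32))
        a = extract_features(vol)
        b = extract_features(vol)
        np.testing.assert_array_equal(a.data, b.data)

    def test_2d_features_depend_only_on_their_own_slice(self, rng):
        base = rng.normal(0, 1, (3, 12, 12)).astype(np.float32)
        other = base.copy()
        other[0] += 50.0  # perturb a different slice
        fa = extract_features(ScalarVolume(base))
        fb = extract_features(ScalarVolume(other))
        for name in ("mean2d_r1", "sd2d_r3", "sobel", "elbp_rd", "elbp_ad", "gabor_0"):
            i = fa.channels.index(name)
            np.testing.assert_array_equal(fa.data[i][2], fb.data[i][2])

    def test_3d_features_depend_only_on_adjacent_slices(self, rng):
        base = rng.normal(0, 1, (5, 12, 12)).astype(np.float32)
        other = base.copy()
        other[0] += 50.0  # two slices away from slice 2... slice 0 adj to 1
        fa = extract_features(ScalarVolume(base))
        fb = extract_features(ScalarVolume(other))
        i = fa.channels.index("mean3d_r4")
        np.testing.assert_array_equal(fa.data[i][2:], fb.data[i][2:])
        assert not np.array_equal(fa.data[i][1], fb.data[i][1])

    def test_channel_order_violation_detected(self, rng):
        from handmuscle import FeatureTensor

        vol = ScalarVolume(rng.normal(0, 1, (2, 10, 10)).astype(np.float32))
        ft = extract_features(vol)
        permuted = FeatureTensor(ft.data[::-1].copy(), ft.channels[::-1], ft.spacing)
        assert permuted.channels != CHANNEL_CATALOG
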