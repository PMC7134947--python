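import numpy as np
import pytest

from hyperphen.envi import Unit
from hyperphen.reflectance import (
    KEEP_RANGE_NM,
    Spectrum,
    aggregate_plot,
    join_cameras,
    mask_bands,
    plot_reflectance_pipeline,
    savgol_smooth,
    to_reflectance,
)
from hyperphen.simulate import (
    SceneConfig,
    default_leaf_reflectance,
    nir_grid,
    simulate_scene,
    vnir_grid,
)


def _spec(wl, vals, unit=Unit.RADIANCE):
    return Spectrum(np.asarray(wl, float), np.asarray(vals, float), unit)


class TestToReflectance:
    def test_ratio_identity(self):
        panel = _spec([500, 600], [3.0, 5.0])
        out = to_reflectance(np.array([[3.0, 5.0]]), panel, 0.99)
        np.testing.assert_allclose(out, 0.99)

    def test_zero_radiance_gives_zero(self):
        panel = _spec([500, 600], [3.0, 5.0])
        assert np.all(to_reflectance(np.zeros((2, 2)), panel, 0.99) == 0.0)

    def test_stated_arithmetic(self):
        """R = (20/100)*0.99 = 0.198 and (40/80)*0.99 = 0.495."""
        panel = _spec([500, 600], [100.0, 80.0])
        out = to_reflectance(np.array([[20.0, 40.0]]), panel,
                             np.array([0.99, 0.99]))
        np.testing.assert_allclose(out[0], [0.198, 0.495])

    def test_zero_panel_band_names_the_band(self):
        panel = _spec([500, 600], [3.0, 0.0])
        with pytest.raises(ZeroDivisionError, match="600"):
            to_reflectance(np.ones((1, 2)), panel, 0.99)

    def test_global_illumination_cancels(self, rng):
        """Scaling both target and panel radiance by c > 0 leaves
        reflectance unchanged."""
        wl = 400.0 + np.arange(20.0)
        panel_v = rng.uniform(1.0, 2.0, 20)
        pix = rng.uniform(0.1, 1.0, size=(5, 20))
        base = to_reflectance(pix, _spec(wl, panel_v), 0.99)
        scaled = to_reflectance(7.3 * pix, _spec(wl, 7.3 * panel_v), 0.99)
        np.testing.assert_allclose(base, scaled, rtol=1e-12)


class TestSavgol:
    def test_constant_unchanged(self):
        s = _spec(np.arange(30.0), np.full(30, 0.4), Unit.REFLECTANCE)
        np.testing.assert_allclose(savgol_smooth(s).values, 0.4)

    def test_quadratic_reproduced(self):
        """An order-2 filter reproduces any degree-<=2 polynomial."""
        x = np.arange(40.0)
        s = _spec(x, 0.01 * x**2 - 0.3 * x + 2.0, Unit.REFLECTANCE)
        np.testing.assert_allclose(savgol_smooth(s).values[5:-5],
                                   s.values[5:-5], atol=1e-10)

    def test_noise_variance_matches_kernel_norm(self):
        """Interior output variance of unit white noise equals the
        squared norm of the window-11/order-2 kernel, computed from the
        least-squares design matrix."""
        offsets = np.arange(-5, 6, dtype=float)
        A = np.vander(offsets, 3, increasing=True)  # [1, x, x^2]
        kernel = (np.linalg.inv(A.T @ A) @ A.T)[0]  # value at x=0
        expected_var = float(kernel @ kernel)

        rng = np.random.default_rng(0)
        draws = rng.normal(size=(100_000, 31))
        from scipy.signal import savgol_filter

        smoothed = savgol_filter(draws, 11, 2, axis=1, mode="interp")
        got = float(np.var(smoothed[:, 15]))
        assert got == pytest.approx(expected_var, rel=0.02)

    def test_too_short_spectrum_rejected(self):
        s = _spec(np.arange(5.0), np.ones(5), Unit.REFLECTANCE)
        with pytest.raises(ValueError, match="window"):
            savgol_smooth(s)


class TestMaskBands:
    def test_identity_inside_keep_range(self):
        wl = np.linspace(500, 1200, 50)
        s = _spec(wl, np.ones(50), Unit.REFLECTANCE)
        out = mask_bands(s)
        np.testing.assert_array_equal(out.wavelengths_nm, wl)

    def test_vnir_grid_against_enumeration_oracle(self):
        wl = vnir_grid()
        s = _spec(wl, np.ones(wl.size), Unit.REFLECTANCE)
        out = mask_bands(s)
        expected = [w for w in wl if 450.0 <= w <= 1700.0
                    and not (1313.0 <= w <= 1440.0)]
        np.testing.assert_allclose(out.wavelengths_nm, expected)

    def test_water_band_boundaries_inclusive(self):
        wl = np.array([1310.0, 1313.0, 1440.0, 1443.0])
        out = mask_bands(_spec(wl, np.ones(4), Unit.REFLECTANCE))
        np.testing.assert_array_equal(out.wavelengths_nm, [1310.0, 1443.0])

    def test_keep_boundaries_inclusive(self):
        wl = np.array([449.0, 450.0, 1700.0, 1701.0])
        out = mask_bands(_spec(wl, np.ones(4), Unit.REFLECTANCE))
        np.testing.assert_array_equal(out.wavelengths_nm, [450.0, 1700.0])

    def test_all_masked_is_error(self):
        s = _spec([400.0, 410.0], [1.0, 1.0], Unit.REFLECTANCE)
        with pytest.raises(ValueError, match="every band"):
            mask_bands(s)


class TestJoinCameras:
    def test_disjoint_grids_concatenate(self):
        v = _spec([500.0, 600.0], [0.1, 0.2], Unit.REFLECTANCE)
        n = _spec([1000.0, 1100.0], [0.3, 0.4], Unit.REFLECTANCE)
        out = join_cameras(v, n)
        np.testing.assert_array_equal(out.wavelengths_nm,
                                      [500, 600, 1000, 1100])
        np.testing.assert_array_equal(out.values, [0.1, 0.2, 0.3, 0.4])

    def test_crossover_band_comes_from_nir(self):
        v = _spec([880.0, 900.0], [0.1, 0.5], Unit.REFLECTANCE)
        n = _spec([900.0, 950.0], [0.3, 0.4], Unit.REFLECTANCE)
        out = join_cameras(v, n)
        np.testing.assert_array_equal(out.wavelengths_nm, [880, 900, 950])
        assert out.values[1] == 0.3  # NIR wins at/above 900

    def test_continuous_endmember_has_no_step(self):
        """Both cameras sampling one continuous reflectance function
        join into that function on the union grid."""
        v = _spec(vnir_grid(), default_leaf_reflectance(vnir_grid()),
                  Unit.REFLECTANCE)
        n = _spec(nir_grid(), default_leaf_reflectance(nir_grid()),
                  Unit.REFLECTANCE)
        out = join_cameras(v, n)
        np.testing.assert_allclose(
            out.values, default_leaf_reflectance(out.wavelengths_nm),
            atol=1e-12,
        )
        assert np.all(np.diff(out.wavelengths_nm) > 0)


class TestAggregatePlot:
    def test_identical_pixels(self):
        wl = np.array([500.0, 600.0])
        pix = np.tile([0.2, 0.4], (7, 1))
        ps = aggregate_plot(pix, wl, "plotA")
        np.testing.assert_allclose(ps.mean.values, [0.2, 0.4])
        np.testing.assert_allclose(ps.sd, 0.0, atol=1e-15)
        assert ps.n_pixels == 7 and ps.plot_id == "plotA"

    def test_population_sd_hand_case(self):
        """Two pixels 0.2 and 0.4: mean 0.3, population SD 0.1."""
        ps = aggregate_plot(np.array([[0.2], [0.4]]), np.array([500.0]))
        assert ps.mean.values[0] == pytest.approx(0.3)
        assert ps.sd[0] == pytest.approx(0.1)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError, match="no sunlit"):
            aggregate_plot(np.empty((0, 3)), np.array([1.0, 2.0, 3.0]))


class TestPipelineOrder:
    def test_noiseless_end_to_end_recovers_leaf_reflectance(
        self, noiseless_scene_config
    ):
        cubes, _ = simulate_scene(noiseless_scene_config)
        ps, _ = plot_reflectance_pipeline(cubes, smooth=False, mask=False)
        expected = default_leaf_reflectance(ps.mean.wavelengths_nm) * 0.99 / 0.99
        np.testing.assert_allclose(ps.mean.values, expected, atol=1e-9)

    def test_mask_applied_after_smoothing(self, noiseless_scene_config):
        """The configured order is smooth-then-mask; masked output
        equals masking the smoothed spectrum, not smoothing the masked
        one (the two differ near the mask edges)."""
        cubes, _ = simulate_scene(noiseless_scene_config)
        raw, _ = plot_reflectance_pipeline(cubes, smooth=False, mask=False)
        both, _ = plot_reflectance_pipeline(cubes, smooth=True, mask=True)
        smooth_then_mask = mask_bands(savgol_smooth(raw.mean))
        np.testing.assert_allclose(both.mean.values, smooth_then_mask.values,
                                   atol=1e-12)
        mask_then_smooth = savgol_smooth(mask_bands(raw.mean))
        assert not np.allclose(both.mean.values, mask_then_smooth.values)

    def test_panel_self_consistency(self, noiseless_scene_config):
        """Reflectance of the panel pixels themselves equals the
        lab-calibrated panel reflectance."""
        from hyperphen.segment import (
            assign_semantics, extract_class_spectra, kmeans_segment,
        )
        cubes, _ = simulate_scene(noiseless_scene_config)
        cube = cubes["vnir"]
        cmap = assign_semantics(kmeans_segment(cube, k=6, seed=0), cube)
        panel_pix = extract_class_spectra(cube, cmap, "panel")
        panel = Spectrum(cube.wavelengths_nm, panel_pix.mean(axis=0),
                         Unit.RADIANCE)
        refl = to_reflectance(panel_pix, panel, 0.99)
        np.testing.assert_allclose(refl, 0.99, atol=1e-9)

    def test_single_camera_run_masks_to_900(self):
        cfg = SceneConfig(lines=40, samples=40, seed=3)
        cubes, _ = simulate_scene(cfg)
        ps, _ = plot_reflectance_pipeline({"vnir": cubes["vnir"]})
        assert ps.mean.wavelengths_nm[0] >= 450.0
        assert ps.mean.wavelengths_nm[-1] <= 900.0
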