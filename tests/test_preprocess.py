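import numpy as np
import pytest

from specrestore.dataset import HyperCube, SpectrumSet, WavenumberAxis
from specrestore.filters import SNIPParams
from specrestore.preprocess import (
    NormalizationState,
    TrimSpec,
    atmospheric_correct,
    build_targets,
    denormalize_stage,
    integrated_band_image,
    inverse_snv,
    minmax_apply,
    minmax_fit,
    minmax_invert,
    normalize_stage,
    otsu_mask,
    snv,
    trim,
)


def _cube_from_scalars(scalars: np.ndarray, axis: WavenumberAxis) -> HyperCube:
    """Cube whose integrated fingerprint intensity equals `scalars` (per pixel)."""
    in_band = axis.indices_in(1000.0, 1800.0)
    data = np.zeros(scalars.shape + (axis.n_points,))
    data[..., in_band[0]] = scalars
    return HyperCube(axis=axis, data=data)


class TestOtsuMask:
    def test_bimodal_split(self, small_axis):
        scalars = np.concatenate([np.zeros(50), np.full(50, 10.0)]).reshape(10, 10)
        cube = _cube_from_scalars(scalars, small_axis)
        mask = otsu_mask(cube)
        np.testing.assert_array_equal(mask, scalars > 5)

    def test_threshold_matches_brute_force(self, small_axis, rng):
        # exhaustive between-class-variance oracle over histogram bins
        scalars = np.concatenate([
            rng.normal(2.0, 0.4, size=60), rng.normal(8.0, 0.6, size=40)
        ]).reshape(10, 10)
        cube = _cube_from_scalars(scalars, small_axis)
        mask = otsu_mask(cube)

        counts, edges = np.histogram(scalars.ravel(), bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        best_var, best_threshold = -1.0, None
        for cut in range(1, 256):
            w1, w2 = counts[:cut].sum(), counts[cut:].sum()
            if w1 == 0 or w2 == 0:
                continue
            m1 = (counts[:cut] * centers[:cut]).sum() / w1
            m2 = (counts[cut:] * centers[cut:]).sum() / w2
            var = w1 * w2 * (m1 - m2) ** 2
            if var > best_var:
                best_var, best_threshold = var, (centers[cut - 1] + centers[cut]) / 2
        np.testing.assert_array_equal(mask, scalars > best_threshold)

    def test_degenerate_error(self, small_axis):
        cube = _cube_from_scalars(np.full((4, 4), 3.0), small_axis)
        with pytest.raises(ValueError, match="no Otsu threshold"):
            otsu_mask(cube)


class TestAtmosphericCorrect:
    def test_shared_artifact_removed(self, small_axis, rng):
        artifact = rng.normal(size=small_axis.n_points)
        clean = np.abs(rng.normal(size=small_axis.n_points)) + 1.0
        data = np.zeros((2, 2, small_axis.n_points))
        mask = np.array([[True, False], [False, False]])
        data[0, 0] = clean + artifact
        data[0, 1] = data[1, 0] = data[1, 1] = artifact
        cube = HyperCube(axis=small_axis, data=data)
        corrected = atmospheric_correct(cube, mask)
        np.testing.assert_allclose(corrected.data[0, 0], clean, atol=1e-12)
        np.testing.assert_array_equal(corrected.data[1, 1], artifact)  # untouched

    def test_zero_background_is_identity(self, small_axis, rng):
        data = rng.normal(size=(2, 2, small_axis.n_points))
        data[1] = 0.0
        mask = np.array([[True, True], [False, False]])
        cube = HyperCube(axis=small_axis, data=data)
        corrected = atmospheric_correct(cube, mask)
        np.testing.assert_array_equal(corrected.data[0], data[0])

    def test_empty_background_error(self, small_axis, rng):
        cube = HyperCube(axis=small_axis, data=rng.normal(size=(2, 2, 128)))
        with pytest.raises(ValueError, match="background"):
            atmospheric_correct(cube, np.ones((2, 2), dtype=bool))

    def test_water_vapor_lines_suppressed_in_synthetic_cube(self):
        from specrestore.synthetic import SyntheticConfig, make_cube

        cfg = SyntheticConfig(
            n_points=256, seed=21, noise_sigma0=0.0, baseline_scale=0.0,
            oscillation_amplitude=0.0, water_vapor_amplitude=0.5,
            scatter_range=(1.0, 1.0),
        )
        cube = make_cube(cfg, height=16, width=16, substrate_level=0.0)
        corrected = atmospheric_correct(cube, cube.mask)
        # the shared lines live in 1300-1900 minus real bands; probe 1750-1900
        probe = cube.axis.indices_in(1750.0, 1900.0)
        before = np.abs(cube.data[cube.mask][:, probe]).max()
        after = np.abs(
            corrected.data[cube.mask][:, probe]
            - corrected.data[cube.mask][:, probe].mean()
        ).max()
        assert before > 10 * after


class TestTrim:
    def test_co2_exclusion_counts(self):
        cfg_axis = WavenumberAxis(np.linspace(950.0, 4000.0, 1584))
        n_excluded = cfg_axis.indices_in(2250.0, 2401.0).size
        spectra = SpectrumSet(
            axis=cfg_axis, intensities=np.ones((2, 1584))
        )
        trimmed = trim(spectra, TrimSpec(excluded=((2250.0, 2401.0),)))
        assert trimmed.axis.n_points == 1584 - n_excluded
        assert n_excluded > 0

    def test_empty_spec_identity(self, random_spectra):
        out = trim(random_spectra, TrimSpec())
        np.testing.assert_array_equal(out.intensities, random_spectra.intensities)

    def test_excluded_wavenumbers_absent(self, random_spectra):
        out = trim(random_spectra, TrimSpec(excluded=((1500.0, 2000.0),)))
        values = out.axis.values
        assert not np.any((values >= 1500.0) & (values <= 2000.0))

    def test_disjoint_trims_commute(self, random_spectra):
        a = TrimSpec(excluded=((1200.0, 1400.0),))
        b = TrimSpec(excluded=((2500.0, 2700.0),))
        ab = trim(trim(random_spectra, a), b)
        ba = trim(trim(random_spectra, b), a)
        np.testing.assert_array_equal(ab.intensities, ba.intensities)
        np.testing.assert_array_equal(ab.axis.values, ba.axis.values)

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TrimSpec(excluded=((1000.0, 1500.0), (1400.0, 1600.0)))

    def test_trim_everything_error(self, random_spectra):
        with pytest.raises(ValueError, match="fewer than 8"):
            trim(random_spectra, TrimSpec(edge_bounds=(100.0, 101.0)))


class TestSNV:
    def test_three_point_example(self):
        out, mean, sd = snv(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])  # sample sd = 1
        assert mean[0] == pytest.approx(2.0)
        assert sd[0] == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(3, 64))
        a, b = 2.5, -7.0
        out_x, _, _ = snv(x)
        out_affine, _, _ = snv(a * x + b)
        np.testing.assert_allclose(out_affine, out_x, atol=1e-10)

    def test_round_trip(self, rng):
        x = rng.normal(size=(4, 64))
        out, mean, sd = snv(x)
        np.testing.assert_allclose(inverse_snv(out, mean, sd), x, rtol=1e-12)

    def test_constant_row_error_names_row(self, rng):
        x = rng.normal(size=(3, 16))
        x[1] = 4.2
        with pytest.raises(ValueError, match="row 1"):
            snv(x)


class TestMinMax:
    def test_midpoint(self):
        assert minmax_apply(np.array([1.0]), (0.0, 2.0))[0] == pytest.approx(0.5)

    def test_held_out_not_clipped(self):
        assert minmax_apply(np.array([3.0]), (0.0, 2.0))[0] == pytest.approx(1.5)

    def test_round_trip(self, rng):
        x = rng.normal(size=(3, 32))
        bounds = minmax_fit(x)
        np.testing.assert_allclose(
            minmax_invert(minmax_apply(x, bounds), bounds), x, rtol=1e-12
        )

    def test_degenerate_bounds_error(self):
        with pytest.raises(ValueError, match="max == min"):
            minmax_fit(np.ones((2, 4)))


class TestNormalizationState:
    def test_full_pipeline_invertible(self, rng):
        x = rng.normal(size=(6, 100)) * 3 + 1
        out, state = normalize_stage(x, "stage1")
        back = denormalize_stage(out, state)
        np.testing.assert_allclose(back, x, rtol=1e-12)

    def test_json_round_trip(self, tmp_path, rng):
        x = rng.normal(size=(3, 32))
        _, state = normalize_stage(x, "stage2")
        path = tmp_path / "state.json"
        state.to_json(path)
        back = NormalizationState.from_json(path)
        np.testing.assert_array_equal(back.snv_mean, state.snv_mean)
        assert back.stage == "stage2"
        assert back.bounds == state.bounds

    def test_invalid_stage_rejected(self, rng):
        with pytest.raises(ValueError, match="stage"):
            NormalizationState(
                snv_mean=np.zeros(2), snv_sd=np.ones(2), stage="stage3",
                global_min=0.0, global_max=1.0,
            )


class TestBuildTargets:
    def test_zero_baseline_targets_agree(self, quiet_config, rng):
        from specrestore.synthetic import clean_spectrum, make_axis

        axis = make_axis(quiet_config)
        rows = np.array([clean_spectrum(quiet_config, rng, axis) for _ in range(3)])
        rows += 0.01 * rng.random(rows.shape)  # avoid constant corrected rows
        hq = SpectrumSet(axis=axis, intensities=rows)
        snip = SNIPParams(max_half_window=12)
        target_a, state_a, target_b, state_b = build_targets(hq, snip)
        # pre-normalization: corrected ~ raw since the baseline is ~ 0
        raw_a = denormalize_stage(target_a.intensities, state_a)
        raw_b = denormalize_stage(target_b.intensities, state_b)
        assert np.abs(raw_a - raw_b).max() < 0.06 * rows.max()

    def test_linear_ramp_baseline_removed(self, quiet_config, rng):
        from specrestore.synthetic import Peak, clean_spectrum, make_axis

        axis = make_axis(quiet_config)
        peak = Peak(1655.0, 20.0, 1.0).profile(axis.values)
        ramp = np.linspace(0.5, 2.0, axis.n_points)
        rows = np.vstack([peak + ramp, 0.8 * peak + ramp])
        hq = SpectrumSet(axis=axis, intensities=rows)
        target_a, state_a, target_b, state_b = build_targets(
            hq, SNIPParams(max_half_window=12)
        )
        raw_b = denormalize_stage(target_b.intensities, state_b)
        # recovered peak height within 5% of the true (sampled) height
        assert raw_b[0].max() == pytest.approx(peak.max(), rel=0.05)
        assert raw_b[1].max() == pytest.approx(0.8 * peak.max(), rel=0.05)

    def test_stage_labels(self, rng, small_axis):
        hq = SpectrumSet(axis=small_axis, intensities=rng.random((3, 128)) + 0.1)
        _, state_a, _, state_b = build_targets(hq, SNIPParams(max_half_window=8))
        assert state_a.stage == "stage1"
        assert state_b.stage == "stage2"
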