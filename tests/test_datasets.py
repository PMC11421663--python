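import numpy as np
import pytest

from blunmix.basis import SpectralGrid
from blunmix.datasets import (
    MeasurementSeries,
    PseudoRealSpec,
    SamplingRanges,
    build_strategy_b,
    derive_ranges_from_fits,
    differential_attenuations,
    generate_pseudo_real,
    load_series,
    load_training_set,
    normalize_raw,
    sample_strategy_a,
    save_series,
    save_training_set,
    spatial_delta_cube,
)
from blunmix.forward import DeltaComposition, forward_delta_attenuation
from blunmix.presets import sampling_ranges
from blunmix.solvers import SolveConfig, solve_batch


class TestNormalizeRaw:
    def _series(self, grid, spectra, dark, white):
        return MeasurementSeries(
            mode="time_series", grid=grid, spectra=spectra, baseline_index=0,
            dark_reference=dark, white_reference=white,
        )

    def test_white_maps_to_one_dark_to_zero(self):
        grid = SpectralGrid.linspace(700.0, 800.0, 5)
        dark = np.full(5, 0.1)
        white = np.full(5, 0.9)
        series = self._series(grid, np.vstack([white, dark]), dark, white)
        out = normalize_raw(series)
        assert np.allclose(out.spectra[0], 1.0, atol=1e-12)
        assert np.allclose(out.spectra[1], 0.0, atol=1e-12)
        assert not out.has_references

    def test_elementwise_oracle(self, rng):
        grid = SpectralGrid.linspace(700.0, 800.0, 7)
        dark = rng.uniform(0.0, 0.1, size=7)
        white = dark + rng.uniform(0.5, 1.0, size=7)
        spectra = rng.uniform(0.2, 0.8, size=(4, 7))
        out = normalize_raw(self._series(grid, spectra, dark, white))
        for t in range(4):
            for j in range(7):
                expected = (spectra[t, j] - dark[j]) / (white[j] - dark[j])
                assert out.spectra[t, j] == pytest.approx(expected, abs=1e-12)

    def test_white_not_above_dark_names_wavelength(self):
        grid = SpectralGrid(np.array([700.0, 750.0]))
        dark = np.array([0.1, 0.5])
        white = np.array([0.9, 0.5])
        series = self._series(grid, np.ones((2, 2)) * 0.4, dark, white)
        with pytest.raises(ValueError, match="750.0 nm"):
            normalize_raw(series)

    def test_missing_references_rejected(self):
        grid = SpectralGrid.linspace(700.0, 800.0, 5)
        series = MeasurementSeries(
            mode="time_series", grid=grid, spectra=np.ones((2, 5)), baseline_index=0
        )
        with pytest.raises(ValueError, match="references"):
            normalize_raw(series)


class TestDifferentialAttenuations:
    def test_identical_to_baseline_gives_zero(self):
        grid = SpectralGrid.linspace(700.0, 800.0, 5)
        spectra = np.tile(np.linspace(0.4, 0.6, 5), (3, 1))
        series = MeasurementSeries(mode="time_series", grid=grid, spectra=spectra, baseline_index=0)
        out = differential_attenuations(series)
        assert len(out) == 2
        for s in out:
            assert np.allclose(s.delta_A, 0.0, atol=1e-14)

    def test_ln_unit_step(self):
        grid = SpectralGrid.linspace(700.0, 800.0, 5)
        base = np.linspace(0.2, 0.3, 5)
        series = MeasurementSeries(
            mode="time_series", grid=grid, spectra=np.vstack([base, base * np.e]),
            baseline_index=0,
        )
        out = differential_attenuations(series)
        assert np.allclose(out[0].delta_A, 1.0, atol=1e-12)

    def test_loop_oracle_over_ten_spectra(self, rng):
        grid = SpectralGrid.linspace(700.0, 800.0, 9)
        spectra = rng.uniform(0.2, 0.9, size=(10, 9))
        series = MeasurementSeries(mode="time_series", grid=grid, spectra=spectra, baseline_index=3)
        out = differential_attenuations(series)
        others = [t for t in range(10) if t != 3]
        assert len(out) == 9
        for s, t in zip(out, others):
            assert np.allclose(s.delta_A, np.log(spectra[t]) - np.log(spectra[3]), atol=1e-14)

    def test_nonpositive_intensity_rejected(self):
        grid = SpectralGrid.linspace(700.0, 800.0, 3)
        spectra = np.array([[0.5, 0.5, 0.5], [0.5, -0.1, 0.5]])
        series = MeasurementSeries(mode="time_series", grid=grid, spectra=spectra, baseline_index=0)
        with pytest.raises(ValueError, match="non-positive"):
            differential_attenuations(series)

    def test_spatial_cube_delta_matches_flat_list(self, rng):
        grid = SpectralGrid.linspace(700.0, 800.0, 6)
        cube = rng.uniform(0.2, 0.9, size=(4, 5, 6))
        series = MeasurementSeries(
            mode="spatial_cube", grid=grid, spectra=cube, baseline_index=(2, 1)
        )
        dcube = spatial_delta_cube(series)
        assert dcube.shape == (4, 5, 6)
        assert np.allclose(dcube[2, 1], 0.0, atol=1e-14)
        flat = differential_attenuations(series, include_baseline=True)
        assert np.allclose(dcube.reshape(20, 6), np.vstack([s.delta_A for s in flat]), atol=1e-14)


class TestStrategyA:
    def test_seeded_determinism(self, nirs_basis_small):
        ranges = sampling_ranges()
        a = sample_strategy_a(ranges, nirs_basis_small, n=50, seed=7)
        b = sample_strategy_a(ranges, nirs_basis_small, n=50, seed=7)
        assert np.array_equal(a.inputs, b.inputs)
        assert np.array_equal(a.targets, b.targets)

    def test_samples_respect_bounds(self, nirs_basis_small):
        ranges = sampling_ranges(model_variant="scattering")
        ts = sample_strategy_a(ranges, nirs_basis_small, n=2000, model_variant="scattering", seed=3)
        for i, name in enumerate(nirs_basis_small.names):
            lo, hi = ranges[name]
            assert ts.targets[:, i].min() >= lo and ts.targets[:, i].max() <= hi
        assert ts.scatter_params is not None
        for j, p in enumerate(("s1", "b1", "s2", "b2")):
            lo, hi = ranges[p]
            assert ts.scatter_params[:, j].min() >= lo and ts.scatter_params[:, j].max() <= hi

    def test_generative_consistency_bitwise(self, nirs_basis_small):
        from blunmix.forward import DeltaComposition, ScatteringParams

        ranges = sampling_ranges(model_variant="scattering")
        ts = sample_strategy_a(ranges, nirs_basis_small, n=25, model_variant="scattering", seed=11)
        for i in range(25):
            comp = DeltaComposition(
                delta_c=dict(zip(ts.names, ts.targets[i].tolist())),
                scatter_before=ScatteringParams(ts.scatter_params[i, 0], ts.scatter_params[i, 1]),
                scatter_after=ScatteringParams(ts.scatter_params[i, 2], ts.scatter_params[i, 3]),
            )
            assert np.array_equal(
                forward_delta_attenuation(comp, nirs_basis_small).delta_A, ts.inputs[i]
            )

    def test_missing_range_rejected(self, nirs_basis_small):
        with pytest.raises(KeyError, match="missing"):
            sample_strategy_a(SamplingRanges({"HbO2": (-0.5, 0.5)}), nirs_basis_small, n=5)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="lo < hi"):
            SamplingRanges({"HbO2": (0.5, -0.5)})


class TestStrategyB:
    def test_targets_are_exactly_solver_outputs(self, nirs_basis_small, rng):
        ranges = sampling_ranges()
        src = sample_strategy_a(ranges, nirs_basis_small, n=30, seed=5)
        spectra = src.spectra()
        noisy = [
            type(s)(grid=s.grid, delta_A=s.delta_A + rng.normal(0, 0.005, size=len(s.grid)))
            for s in spectra
        ]
        cfg = SolveConfig(model_variant="linear")
        ts = build_strategy_b(noisy, nirs_basis_small, cfg)
        fits = solve_batch(noisy, nirs_basis_small, cfg)
        assert np.array_equal(
            ts.targets, np.vstack([f.delta_c_vector(nirs_basis_small.names) for f in fits])
        )
        assert ts.provenance == "strategy_b"

    def test_noiseless_pseudo_real_closure(self, nirs_basis_small):
        spec = PseudoRealSpec(mode="time_series", n_timepoints=40, model_variant="linear")
        series, truth = generate_pseudo_real(spec, nirs_basis_small, seed=2)
        ts = build_strategy_b(series, nirs_basis_small, SolveConfig(model_variant="linear"))
        assert np.allclose(ts.targets, truth.delta_c[1:], atol=1e-6)

    def test_empty_input_rejected(self, nirs_basis_small):
        with pytest.raises(ValueError, match="no non-baseline"):
            build_strategy_b([], nirs_basis_small)


class TestDeriveRanges:
    def _fits(self, basis, dcs):
        spectra = [
            forward_delta_attenuation(
                DeltaComposition(delta_c=dict(zip(basis.names, dc))), basis
            )
            for dc in dcs
        ]
        return solve_batch(spectra, basis, SolveConfig(model_variant="linear"))

    def test_two_point_min_max(self, nirs_basis_small):
        fits = self._fits(nirs_basis_small, [[0.1, 0.0, 0.0], [0.3, 0.0, 0.0]])
        ranges = derive_ranges_from_fits(fits, nirs_basis_small.names)
        lo, hi = ranges["HbO2"]
        assert lo == pytest.approx(0.1, abs=1e-8)
        assert hi == pytest.approx(0.3, abs=1e-8)

    def test_hundred_fit_min_max_oracle(self, nirs_basis_small, rng):
        dcs = rng.uniform(-0.4, 0.4, size=(100, 3)).tolist()
        fits = self._fits(nirs_basis_small, dcs)
        ranges = derive_ranges_from_fits(fits, nirs_basis_small.names)
        recovered = np.vstack([f.delta_c_vector(nirs_basis_small.names) for f in fits])
        for i, name in enumerate(nirs_basis_small.names):
            assert ranges[name][0] == pytest.approx(recovered[:, i].min(), abs=1e-12)
            assert ranges[name][1] == pytest.approx(recovered[:, i].max(), abs=1e-12)

    def test_single_fit_rejected(self, nirs_basis_small):
        fits = self._fits(nirs_basis_small, [[0.1, 0.0, 0.0]])
        with pytest.raises(ValueError, match="at least 2"):
            derive_ranges_from_fits(fits, nirs_basis_small.names)

    def test_degenerate_range_widened(self, nirs_basis_small):
        fits = self._fits(nirs_basis_small, [[0.1, 0.2, 0.0], [0.1, 0.3, 0.0]])
        ranges = derive_ranges_from_fits(fits, nirs_basis_small.names, epsilon=1e-6)
        lo, hi = ranges["diffCCO"]
        assert lo < hi  # widened around the degenerate value


class TestPseudoReal:
    def test_time_series_seeded_determinism(self, nirs_basis_small):
        spec = PseudoRealSpec(mode="time_series", n_timepoints=30, noise_sigma=0.01)
        s1, t1 = generate_pseudo_real(spec, nirs_basis_small, seed=4)
        s2, t2 = generate_pseudo_real(spec, nirs_basis_small, seed=4)
        assert np.array_equal(s1.spectra, s2.spectra)
        assert np.array_equal(t1.delta_c, t2.delta_c)

    def test_baseline_truth_is_zero(self, nirs_basis_small):
        spec = PseudoRealSpec(mode="time_series", n_timepoints=30)
        series, truth = generate_pseudo_real(spec, nirs_basis_small, seed=4)
        assert series.baseline_index == 0
        assert np.allclose(truth.delta_c[0], 0.0, atol=1e-12)

    def test_references_roundtrip(self, nirs_basis_small):
        spec = PseudoRealSpec(mode="time_series", n_timepoints=20, with_references=True)
        raw, truth = generate_pseudo_real(spec, nirs_basis_small, seed=9)
        bare, _ = generate_pseudo_real(
            PseudoRealSpec(mode="time_series", n_timepoints=20, with_references=False),
            nirs_basis_small,
            seed=9,
        )
        assert raw.has_references
        normalized = normalize_raw(raw)
        assert np.allclose(normalized.spectra, bare.spectra, atol=1e-12)

    def test_spatial_cube_structure(self, hsi_basis_small):
        spec = PseudoRealSpec(mode="spatial_cube", shape=(12, 16), model_variant="scattering")
        series, truth = generate_pseudo_real(spec, hsi_basis_small, seed=1)
        assert series.mode == "spatial_cube"
        assert series.spectra.shape == (12, 16, len(hsi_basis_small.grid))
        r, c = series.baseline_index
        assert truth.region_labels is not None
        assert truth.region_labels[r, c] == 0  # baseline pixel sits in the vessel region
        assert set(np.unique(truth.region_labels)) == {0, 1, 2}
        assert np.allclose(truth.delta_c[r, c], 0.0, atol=1e-12)

    def test_noise_ramp_increases_red_edge_variance(self, nirs_basis_small):
        spec = PseudoRealSpec(
            mode="time_series", n_timepoints=600, noise_sigma=0.02, noise_ramp=3.0
        )
        series, _ = generate_pseudo_real(spec, nirs_basis_small, seed=6)
        clean, _ = generate_pseudo_real(
            PseudoRealSpec(mode="time_series", n_timepoints=600), nirs_basis_small, seed=6
        )
        resid = series.spectra - clean.spectra
        assert resid[:, -1].std() > 2.0 * resid[:, 0].std()


class TestIO:
    def test_series_roundtrip(self, nirs_basis_small, tmp_path):
        spec = PseudoRealSpec(mode="time_series", n_timepoints=15, with_references=True)
        series, _ = generate_pseudo_real(spec, nirs_basis_small, seed=8)
        path = tmp_path / "series.h5"
        save_series(series, path)
        back = load_series(path)
        assert back.mode == series.mode
        assert back.baseline_index == series.baseline_index
        assert np.array_equal(back.spectra, series.spectra)
        assert np.array_equal(back.dark_reference, series.dark_reference)
        assert np.array_equal(back.white_reference, series.white_reference)

    def test_cube_roundtrip(self, hsi_basis_small, tmp_path):
        spec = PseudoRealSpec(mode="spatial_cube", shape=(6, 8))
        series, _ = generate_pseudo_real(spec, hsi_basis_small, seed=8)
        path = tmp_path / "cube.h5"
        save_series(series, path)
        back = load_series(path)
        assert back.baseline_index == series.baseline_index
        assert np.array_equal(back.spectra, series.spectra)

    def test_training_set_roundtrip(self, nirs_basis_small, tmp_path):
        ts = sample_strategy_a(
            sampling_ranges(model_variant="scattering"),
            nirs_basis_small, n=20, model_variant="scattering", seed=13,
        )
        path = tmp_path / "train.h5"
        save_training_set(ts, path)
        back = load_training_set(path)
        assert np.array_equal(back.inputs, ts.inputs)
        assert np.array_equal(back.targets, ts.targets)
        assert np.array_equal(back.scatter_params, ts.scatter_params)
        assert back.names == ts.names
        assert back.provenance == ts.provenance
        assert back.seed == ts.seed
        assert np.array_equal(back.normalization.input_mean, ts.normalization.input_mean)
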