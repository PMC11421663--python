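import numpy as np
import pandas as pd
import pytest

from blunmix.basis import SpectralGrid
from blunmix.datasets import PseudoRealSpec, generate_pseudo_real, sample_strategy_a
from blunmix.evaluation import (
    ChromophoreMap,
    EvaluationReport,
    SolverEngine,
    band_improvement_histogram,
    concentration_mae,
    infer_maps,
    relative_improvement,
    spectral_mae,
)
from blunmix.forward import AttenuationSpectrum
from blunmix.presets import sampling_ranges
from blunmix.solvers import SolveConfig
from blunmix.surrogate import SurrogateConfig, train


def _spec(grid, values):
    return AttenuationSpectrum(grid=grid, delta_A=np.asarray(values, dtype=float))


class TestSpectralMAE:
    grid = SpectralGrid.linspace(700.0, 800.0, 11)

    def test_identical_spectra_zero(self, rng):
        a = _spec(self.grid, rng.normal(size=11))
        assert spectral_mae(a, a) == 0.0

    def test_constant_offset(self):
        a = _spec(self.grid, np.zeros(11))
        b = _spec(self.grid, np.full(11, 0.5))
        assert spectral_mae(a, b) == pytest.approx(0.5)

    def test_loop_oracle(self, rng):
        x, y = rng.normal(size=(2, 11))
        got = spectral_mae(_spec(self.grid, x), _spec(self.grid, y))
        expected = sum(abs(xi - yi) for xi, yi in zip(x, y)) / 11
        assert got == pytest.approx(expected, abs=1e-12)

    def test_band_restriction(self):
        a = _spec(self.grid, np.zeros(11))
        vals = np.zeros(11)
        vals[:5] = 1.0  # 700-740 nm
        b = _spec(self.grid, vals)
        assert spectral_mae(a, b, band=(750.0, 800.0)) == 0.0
        assert spectral_mae(a, b, band=(700.0, 740.0)) == pytest.approx(1.0)

    def test_empty_band_error(self):
        a = _spec(self.grid, np.zeros(11))
        with pytest.raises(ValueError, match="no grid wavelengths"):
            spectral_mae(a, a, band=(900.0, 950.0))

    def test_symmetry_and_triangle_bound(self, rng):
        x, y, z = rng.normal(size=(3, 11))
        a, b, c = _spec(self.grid, x), _spec(self.grid, y), _spec(self.grid, z)
        assert spectral_mae(a, b) == spectral_mae(b, a)
        assert spectral_mae(a, c) <= spectral_mae(a, b) + spectral_mae(b, c) + 1e-12

    def test_grid_mismatch_rejected(self):
        a = _spec(self.grid, np.zeros(11))
        b = _spec(SpectralGrid.linspace(700.0, 800.0, 12), np.zeros(12))
        with pytest.raises(ValueError, match="different wavelength grids"):
            spectral_mae(a, b)


class TestRelativeImprovement:
    def test_equal_maes_zero(self):
        assert relative_improvement(0.3, 0.3) == 0.0

    def test_halving(self):
        assert relative_improvement(0.5 * 0.4, 0.4) == pytest.approx(-0.5)

    def test_scalar_oracle(self):
        # hand computation: (0.021 - 0.030) / 0.030 = -0.3
        assert relative_improvement(0.021, 0.030) == pytest.approx(-0.3)

    def test_zero_linear_mae_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            relative_improvement(0.1, 0.0)

    def test_negative_mae_rejected(self):
        with pytest.raises(ValueError):
            relative_improvement(-0.1, 0.2)


class TestConcentrationMAE:
    def test_identical_zero(self, rng):
        x = rng.normal(size=(5, 3))
        assert concentration_mae(x, x) == 0.0

    def test_single_record_scalar(self):
        assert concentration_mae(np.array([[0.5]]), np.array([[0.3]])) == pytest.approx(0.2)

    def test_flattened_mean_oracle(self, rng):
        a, b = rng.normal(size=(2, 7, 4))
        assert concentration_mae(a, b) == pytest.approx(np.abs(a - b).ravel().mean(), abs=1e-14)

    def test_per_chromophore(self, rng):
        a, b = rng.normal(size=(2, 7, 4))
        per = concentration_mae(a, b, per_chromophore=True)
        assert per.shape == (4,)
        assert np.allclose(per, np.abs(a - b).mean(axis=0), atol=1e-14)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            concentration_mae(np.zeros((2, 3)), np.zeros((3, 2)))


class TestInferMaps:
    def test_uniform_cube_gives_zero_maps(self, hsi_basis_small):
        grid = hsi_basis_small.grid
        base = np.linspace(0.4, 0.6, len(grid))
        cube = np.tile(base, (5, 6, 1))
        from blunmix.datasets import MeasurementSeries

        series = MeasurementSeries(mode="spatial_cube", grid=grid, spectra=cube,
                                   baseline_index=(2, 3))
        engine = SolverEngine(basis=hsi_basis_small, config=SolveConfig(model_variant="linear"))
        maps = infer_maps(series, engine)
        assert {"delta_HbT", "delta_diffCCO"} <= set(maps)
        for m in maps.values():
            assert np.allclose(m.values, 0.0, atol=1e-10)

    def test_planted_cube_recovered_pixelwise_and_ordered(self, hsi_basis_small):
        spec = PseudoRealSpec(mode="spatial_cube", shape=(8, 8), model_variant="linear")
        series, truth = generate_pseudo_real(spec, hsi_basis_small, seed=3)
        engine = SolverEngine(basis=hsi_basis_small, config=SolveConfig(model_variant="linear"))
        maps = infer_maps(series, engine)
        for i, name in enumerate(hsi_basis_small.names):
            assert np.allclose(maps[name].values, truth.delta_c[..., i], atol=1e-6)
        hbt = maps["delta_HbT"]
        m1 = hbt.region_mean(truth.region_labels == 1)
        m2 = hbt.region_mean(truth.region_labels == 2)
        assert m2 > m1 > 0  # region 2 planted with the larger hemoglobin excess

    def test_baseline_pixel_exactly_zero(self, hsi_basis_small):
        spec = PseudoRealSpec(mode="spatial_cube", shape=(8, 8), noise_sigma=0.01)
        series, _ = generate_pseudo_real(spec, hsi_basis_small, seed=5)
        engine = SolverEngine(basis=hsi_basis_small, config=SolveConfig(model_variant="linear"))
        maps = infer_maps(series, engine)
        r, c = series.baseline_index
        for m in maps.values():
            assert m.values[r, c] == 0.0
            assert m.baseline_pixel == (r, c)

    def test_surrogate_engine_agrees_with_solver(self, hsi_basis_small):
        ranges = sampling_ranges(hsi_basis_small.names)
        train_set = sample_strategy_a(ranges, hsi_basis_small, n=3000, seed=31)
        val_set = sample_strategy_a(ranges, hsi_basis_small, n=500, seed=32)
        cfg = SurrogateConfig(hidden_layers=0, width=1, learning_rate=5e-3,
                              max_epochs=500, patience=40, seed=0)
        model, _ = train(train_set, val_set, cfg)

        spec = PseudoRealSpec(mode="spatial_cube", shape=(8, 8), model_variant="linear")
        series, _ = generate_pseudo_real(spec, hsi_basis_small, seed=7)
        solver_maps = infer_maps(
            series, SolverEngine(basis=hsi_basis_small, config=SolveConfig(model_variant="linear"))
        )
        surrogate_maps = infer_maps(series, model)
        for name in hsi_basis_small.names:
            lo, hi = ranges[name]
            mae = np.abs(solver_maps[name].values - surrogate_maps[name].values).mean()
            assert mae <= 0.01 * (hi - lo)

    def test_time_series_rejected(self, nirs_basis_small):
        spec = PseudoRealSpec(mode="time_series", n_timepoints=10)
        series, _ = generate_pseudo_real(spec, nirs_basis_small, seed=0)
        engine = SolverEngine(basis=nirs_basis_small)
        with pytest.raises(ValueError, match="spatial_cube"):
            infer_maps(series, engine)

    def test_map_validation(self):
        with pytest.raises(ValueError, match="baseline pixel"):
            ChromophoreMap(quantity="x", values=np.zeros((3, 3)), baseline_pixel=(5, 0))
        with pytest.raises(ValueError, match="2-D"):
            ChromophoreMap(quantity="x", values=np.zeros(3), baseline_pixel=(0, 0))


class TestHistogram:
    def test_single_individual(self):
        df = band_improvement_histogram({(700.0, 800.0): [-0.12]})
        assert len(df) == 1
        assert df.loc[0, "mean_r"] == pytest.approx(-0.12)
        assert df.loc[0, "count"] == 1

    def test_cohort_mean_matches_direct_average(self, rng):
        values = rng.normal(-0.1, 0.05, size=25).tolist()
        df = band_improvement_histogram({(700.0, 800.0): values})
        assert df["mean_r"].iloc[0] == pytest.approx(np.mean(values), abs=1e-12)
        assert df["count"].sum() == 25

    def test_all_zero_degenerate_single_bin(self):
        df = band_improvement_histogram({(700.0, 800.0): [0.0] * 10})
        assert len(df) == 1
        assert df.loc[0, "bin_lo"] == 0.0
        assert df.loc[0, "count"] == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            band_improvement_histogram({})


class TestReport:
    def _table(self):
        return pd.DataFrame(
            {
                "individual": ["p1", "p2"],
                "spectral_mae_linear": [0.03, 0.02],
                "spectral_mae_scattering": [0.025, 0.018],
                "concentration_mae_strategy_a": [0.01, 0.012],
                "concentration_mae_strategy_b": [0.008, 0.009],
            }
        )

    def test_valid_report_roundtrip(self, tmp_path):
        report = EvaluationReport(table=self._table())
        out = tmp_path / "report.csv"
        report.to_csv(out)
        back = pd.read_csv(out)
        assert list(back.columns) == list(report.table.columns)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            EvaluationReport(table=self._table().drop(columns=["spectral_mae_linear"]))

    def test_overlapping_bands_rejected(self):
        bands = pd.DataFrame(
            {
                "individual": ["p1", "p1"],
                "band_lo_nm": [700.0, 750.0],
                "band_hi_nm": [760.0, 800.0],
                "r": [-0.1, -0.2],
            }
        )
        with pytest.raises(ValueError, match="overlapping"):
            EvaluationReport(table=self._table(), band_improvements=bands)
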