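"""Fit metrics, model-comparison summaries and per-pixel chromophore maps.

The spectral fit is scored by the mean absolute difference between modelled
and measured differential attenuation (optionally over a wavelength band);
the surrogate is scored by concentration MAE against the least-squares
solver's outputs, which serve as ground truth. The relative improvement
r = (MAE_scatter - MAE_linear) / MAE_linear compares the two physics
variants: negative r means the scattering model fits better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .basis import ChromophoreBasis
from .datasets import MeasurementSeries, spatial_delta_cube
from .forward import AttenuationSpectrum
from .solvers import SolveConfig, solve_batch
from .surrogate import SurrogateModel

__all__ = [
    "spectral_mae",
    "relative_improvement",
    "concentration_mae",
    "ChromophoreMap",
    "SolverEngine",
    "infer_maps",
    "band_improvement_histogram",
    "EvaluationReport",
]


def spectral_mae(
    model_dA: AttenuationSpectrum,
    data_dA: AttenuationSpectrum,
    band: tuple[float, float] | None = None,
) -> float:
    """Mean absolute difference of two attenuation spectra over an optional band (nm)."""
    if not np.array_equal(model_dA.grid.wavelengths, data_dA.grid.wavelengths):
        raise ValueError("spectra are on different wavelength grids")
    mask = model_dA.grid.band_mask(band)
    return float(np.mean(np.abs(model_dA.delta_A[mask] - data_dA.delta_A[mask])))


def relative_improvement(mae_scatter: float, mae_linear: float) -> float:
    """r = (MAE_scatter - MAE_linear) / MAE_linear; negative favours scattering."""
    if mae_scatter < 0 or mae_linear < 0:
        raise ValueError("MAEs must be non-negative")
    if mae_linear == 0:
        raise ValueError("relative improvement undefined: linear-model MAE is zero")
    return (mae_scatter - mae_linear) / mae_linear


def concentration_mae(
    predicted: np.ndarray, reference: np.ndarray, per_chromophore: bool = False
) -> float | np.ndarray:
    """Mean absolute concentration error over records (and chromophores).

    With `per_chromophore=True` returns one MAE per chromophore column instead
    of the uniform average over all entries.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {reference.shape}")
    err = np.abs(predicted - reference)
    if per_chromophore:
        return err.mean(axis=0)
    return float(err.mean())


@dataclass(frozen=True)
class ChromophoreMap:
    """Per-pixel derived quantity from a spatial acquisition."""

    quantity: str
    values: np.ndarray  # (H, W)
    baseline_pixel: tuple[int, int]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("map values must be a 2-D array")
        r, c = self.baseline_pixel
        if not (0 <= r < values.shape[0] and 0 <= c < values.shape[1]):
            raise ValueError(f"baseline pixel {self.baseline_pixel} outside map {values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def region_mean(self, mask: np.ndarray) -> float:
        return float(self.values[mask].mean())


@dataclass(frozen=True)
class SolverEngine:
    """Classical least-squares engine for per-pixel unmixing."""

    basis: ChromophoreBasis
    config: SolveConfig = field(default_factory=lambda: SolveConfig(model_variant="linear"))


Engine = Union[SolverEngine, SurrogateModel]


def infer_maps(
    series: MeasurementSeries,
    engine: Engine,
    band: tuple[float, float] | None = None,
) -> dict[str, ChromophoreMap]:
    """Per-pixel concentration-change maps from a spatial cube.

    Every pixel is differenced against the cube's baseline pixel; the chosen
    engine (classical solver or trained surrogate) unmixes each differential
    spectrum. Returns one map per chromophore plus the derived hemodynamic
    map delta_HbT = dHbO2 + dHHb and metabolic map delta_diffCCO
    (= dOxCCO - dRedCCO when both redox states are fitted). The baseline
    pixel's own values are zero by construction.
    """
    if series.mode != "spatial_cube":
        raise ValueError("infer_maps requires a spatial_cube series")
    cube = spatial_delta_cube(series)  # (H, W, L)
    H, W, L = cube.shape
    mask = series.grid.band_mask(band)
    flat = cube.reshape(H * W, L)[:, mask]

    if isinstance(engine, SurrogateModel):
        if engine.input_dim != int(mask.sum()):
            raise ValueError(
                f"surrogate expects {engine.input_dim} wavelengths, cube band has {int(mask.sum())}"
            )
        names = engine.names
        dc = engine.predict_array(flat)
    else:
        basis = engine.basis if band is None else engine.basis.restrict(band)
        if not np.array_equal(basis.grid.wavelengths, series.grid.wavelengths[mask]):
            raise ValueError("engine basis grid does not match the cube's (banded) grid")
        names = basis.names
        from .basis import SpectralGrid

        banded_grid = SpectralGrid(series.grid.wavelengths[mask])
        spectra = [AttenuationSpectrum(grid=banded_grid, delta_A=row) for row in flat]
        fits = solve_batch(spectra, basis, engine.config)
        dc = np.vstack([f.delta_c_vector(names) for f in fits])

    dc = dc.reshape(H, W, len(names))
    br, bc = series.baseline_index  # type: ignore[misc]
    dc[br, bc, :] = 0.0
    maps = {
        name: ChromophoreMap(quantity=name, values=dc[:, :, i], baseline_pixel=(br, bc))
        for i, name in enumerate(names)
    }
    if "HbO2" in maps and "HHb" in maps:
        maps["delta_HbT"] = ChromophoreMap(
            quantity="delta_HbT",
            values=maps["HbO2"].values + maps["HHb"].values,
            baseline_pixel=(br, bc),
        )
    if "oxCCO" in maps and "redCCO" in maps:
        maps["delta_diffCCO"] = ChromophoreMap(
            quantity="delta_diffCCO",
            values=maps["oxCCO"].values - maps["redCCO"].values,
            baseline_pixel=(br, bc),
        )
    elif "diffCCO" in maps:
        maps["delta_diffCCO"] = ChromophoreMap(
            quantity="delta_diffCCO", values=maps["diffCCO"].values, baseline_pixel=(br, bc)
        )
    return maps


def band_improvement_histogram(
    r_by_band: Mapping[tuple[float, float], Sequence[float]], n_bins: int = 10
) -> pd.DataFrame:
    """Distribution of per-individual relative improvements per wavelength band.

    One row per (band, bin) with counts, plus the band's mean r and cohort
    size repeated on each row. A band whose r values are all identical
    degenerates to a single bin centred at that value.
    """
    if not r_by_band:
        raise ValueError("need at least one band")
    rows = []
    for (lo, hi), values in r_by_band.items():
        values = np.asarray(list(values), dtype=float)
        if values.size == 0:
            raise ValueError(f"band ({lo}, {hi}) has no individuals")
        mean_r = float(values.mean())
        if values.min() == values.max():
            rows.append(
                {
                    "band_lo_nm": lo, "band_hi_nm": hi, "n_individuals": values.size,
                    "mean_r": mean_r, "bin_lo": float(values[0]), "bin_hi": float(values[0]),
                    "count": int(values.size),
                }
            )
            continue
        counts, edges = np.histogram(values, bins=n_bins)
        for b in range(n_bins):
            rows.append(
                {
                    "band_lo_nm": lo, "band_hi_nm": hi, "n_individuals": values.size,
                    "mean_r": mean_r, "bin_lo": float(edges[b]), "bin_hi": float(edges[b + 1]),
                    "count": int(counts[b]),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-individual fit/prediction summary.

    `table` columns: individual, spectral_mae_linear, spectral_mae_scattering,
    concentration_mae_strategy_a, concentration_mae_strategy_b. Optional
    `band_improvements` holds per-individual r per wavelength band.
    """

    table: pd.DataFrame
    band_improvements: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {
            "individual",
            "spectral_mae_linear",
            "spectral_mae_scattering",
            "concentration_mae_strategy_a",
            "concentration_mae_strategy_b",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"report table missing columns {sorted(missing)}")
        numeric = self.table.drop(columns=["individual"]).to_numpy(dtype=float)
        if np.any(numeric[np.isfinite(numeric)] < 0):
            raise ValueError("MAEs must be non-negative")
        if self.band_improvements is not None:
            bands = self.band_improvements
            for _, group in bands.groupby("individual"):
                intervals = sorted(zip(group["band_lo_nm"], group["band_hi_nm"]))
                for (alo, ahi), (blo, bhi) in zip(intervals, intervals[1:]):
                    if blo < ahi:
                        raise ValueError(
                            f"overlapping bands ({alo}, {ahi}) and ({blo}, {bhi}) in report row"
                        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
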