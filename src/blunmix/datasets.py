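"""Measurement handling and training-set construction.

Two routes produce (attenuation, concentration) training pairs for the
surrogate:

* **strategy (a)** — sample concentration changes (and, for the scattering
  variant, the four scattering parameters) uniformly from physiological
  ranges and evaluate the forward model; purely synthetic, noise-free.
* **strategy (b)** — run the classical least-squares solver on measured (or
  emulated) differential spectra and pair each spectrum with its fitted
  concentrations, so training data follow the real spectra's distribution.

A pseudo-real generator emulates both acquisition modes (time series with
hypoxia-like excursions; spatial cubes with planted tissue regions and a
vessel baseline pixel) with known ground truth, standing in for instrument
recordings that are not distributable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import h5py
import numpy as np

from .basis import ChromophoreBasis, SpectralGrid
from .forward import AttenuationSpectrum, DeltaComposition, ScatteringParams, forward_delta_attenuation
from .solvers import SCATTER_PARAM_NAMES, FitResult, SolveConfig, solve_batch

__all__ = [
    "SamplingRanges",
    "Normalization",
    "TrainingSet",
    "MeasurementSeries",
    "PseudoRealSpec",
    "GroundTruth",
    "normalize_raw",
    "differential_attenuations",
    "spatial_delta_cube",
    "sample_strategy_a",
    "build_strategy_b",
    "derive_ranges_from_fits",
    "generate_pseudo_real",
    "save_series",
    "load_series",
    "save_training_set",
    "load_training_set",
]

logger = logging.getLogger(__name__)

TIME_SERIES = "time_series"
SPATIAL_CUBE = "spatial_cube"


@dataclass(frozen=True)
class SamplingRanges:
    """Per-parameter uniform sampling intervals (lo, hi)."""

    ranges: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranges", dict(self.ranges))
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {name!r} must have lo < hi, got ({lo}, {hi})")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.ranges[name]

    def __contains__(self, name: str) -> bool:
        return name in self.ranges

    def require(self, names: Sequence[str]) -> None:
        missing = [n for n in names if n not in self.ranges]
        if missing:
            raise KeyError(f"sampling ranges missing parameters {missing}")

    def width(self, name: str) -> float:
        lo, hi = self.ranges[name]
        return hi - lo


@dataclass(frozen=True)
class Normalization:
    """Invertible per-feature affine maps for network inputs and targets."""

    input_mean: np.ndarray
    input_scale: np.ndarray
    target_mean: np.ndarray
    target_scale: np.ndarray

    @classmethod
    def fit(cls, inputs: np.ndarray, targets: np.ndarray) -> "Normalization":
        def _stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            mean = x.mean(axis=0)
            scale = x.std(axis=0)
            scale = np.where(scale > 0, scale, 1.0)  # constant features stay invertible
            return mean, scale

        im, isc = _stats(inputs)
        tm, tsc = _stats(targets)
        return cls(input_mean=im, input_scale=isc, target_mean=tm, target_scale=tsc)

    def normalize_inputs(self, x: np.ndarray) -> np.ndarray:
        return (x - self.input_mean) / self.input_scale

    def normalize_targets(self, y: np.ndarray) -> np.ndarray:
        return (y - self.target_mean) / self.target_scale

    def denormalize_targets(self, y: np.ndarray) -> np.ndarray:
        return y * self.target_scale + self.target_mean


@dataclass(frozen=True)
class TrainingSet:
    """Paired (differential attenuation, concentration change) records.

    `inputs` is (n, n_wavelengths), `targets` is (n, n_chromophores) in the
    order of `names`. `scatter_params` (n, 4: s1, b1, s2, b2) is kept for
    provenance when the generating model included scattering; the surrogate
    predicts concentrations only.
    """

    inputs: np.ndarray
    targets: np.ndarray
    grid: SpectralGrid
    names: tuple[str, ...]
    provenance: Literal["strategy_a", "strategy_b"]
    seed: int | None = None
    normalization: Normalization | None = None
    scatter_params: np.ndarray | None = None

    def __post_init__(self) -> None:
        inputs = np.asarray(self.inputs, dtype=float)
        targets = np.asarray(self.targets, dtype=float)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "names", tuple(self.names))
        if inputs.ndim != 2 or targets.ndim != 2:
            raise ValueError("inputs and targets must be 2-D arrays")
        if inputs.shape[0] != targets.shape[0]:
            raise ValueError(
                f"{inputs.shape[0]} inputs vs {targets.shape[0]} targets"
            )
        if inputs.shape[1] != len(self.grid):
            raise ValueError(f"input width {inputs.shape[1]} != grid length {len(self.grid)}")
        if targets.shape[1] != len(self.names):
            raise ValueError(f"target width {targets.shape[1]} != {len(self.names)} chromophores")
        if self.provenance not in ("strategy_a", "strategy_b"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.normalization is None:
            object.__setattr__(self, "normalization", Normalization.fit(inputs, targets))

    def __len__(self) -> int:
        return int(self.inputs.shape[0])

    def spectra(self) -> list[AttenuationSpectrum]:
        return [AttenuationSpectrum(grid=self.grid, delta_A=row) for row in self.inputs]


@dataclass(frozen=True)
class MeasurementSeries:
    """Intensity spectra from one acquisition, plus the baseline designation.

    `spectra` is (T, L) for time series or (H, W, L) for spatial cubes;
    `baseline_index` is a time index or an (row, col) pixel coordinate.
    Optional dark/white reference spectra live on the same grid.
    """

    mode: Literal["time_series", "spatial_cube"]
    grid: SpectralGrid
    spectra: np.ndarray
    baseline_index: int | tuple[int, int]
    dark_reference: np.ndarray | None = None
    white_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        spectra = np.asarray(self.spectra, dtype=float)
        object.__setattr__(self, "spectra", spectra)
        L = len(self.grid)
        if self.mode == TIME_SERIES:
            if spectra.ndim != 2 or spectra.shape[1] != L:
                raise ValueError(f"time-series spectra must be (T, {L}), got {spectra.shape}")
            idx = int(self.baseline_index)  # type: ignore[arg-type]
            if not 0 <= idx < spectra.shape[0]:
                raise ValueError(f"baseline index {idx} out of range for T={spectra.shape[0]}")
            object.__setattr__(self, "baseline_index", idx)
        elif self.mode == SPATIAL_CUBE:
            if spectra.ndim != 3 or spectra.shape[2] != L:
                raise ValueError(f"cube spectra must be (H, W, {L}), got {spectra.shape}")
            r, c = self.baseline_index  # type: ignore[misc]
            if not (0 <= r < spectra.shape[0] and 0 <= c < spectra.shape[1]):
                raise ValueError(f"baseline pixel {(r, c)} outside {spectra.shape[:2]}")
            object.__setattr__(self, "baseline_index", (int(r), int(c)))
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        for label, ref in (("dark", self.dark_reference), ("white", self.white_reference)):
            if ref is not None:
                ref = np.asarray(ref, dtype=float)
                if ref.shape != (L,):
                    raise ValueError(f"{label} reference shape {ref.shape} != ({L},)")
        if self.dark_reference is not None:
            object.__setattr__(self, "dark_reference", np.asarray(self.dark_reference, dtype=float))
        if self.white_reference is not None:
            object.__setattr__(self, "white_reference", np.asarray(self.white_reference, dtype=float))

    @property
    def has_references(self) -> bool:
        return self.dark_reference is not None and self.white_reference is not None

    def baseline_spectrum(self) -> np.ndarray:
        if self.mode == TIME_SERIES:
            return self.spectra[self.baseline_index]
        r, c = self.baseline_index  # type: ignore[misc]
        return self.spectra[r, c]


def normalize_raw(series: MeasurementSeries) -> MeasurementSeries:
    """Reference-normalise raw intensities: (I - dark) / (white - dark)."""
    if not series.has_references:
        raise ValueError("series lacks dark/white references; nothing to normalise")
    dark = series.dark_reference
    white = series.white_reference
    assert dark is not None and white is not None
    bad = np.flatnonzero(white <= dark)
    if bad.size:
        wl = series.grid.wavelengths[bad[0]]
        raise ValueError(f"white reference <= dark reference at {wl} nm")
    normalized = (series.spectra - dark) / (white - dark)
    return MeasurementSeries(
        mode=series.mode,
        grid=series.grid,
        spectra=normalized,
        baseline_index=series.baseline_index,
        dark_reference=None,
        white_reference=None,
    )


def _check_positive(intensities: np.ndarray, grid: SpectralGrid, where: str) -> None:
    if np.any(intensities <= 0):
        flat = np.argmin(intensities)
        idx = np.unravel_index(flat, intensities.shape)
        wl = grid.wavelengths[idx[-1]]
        raise ValueError(f"non-positive intensity at {where} index {idx[:-1]}, {wl} nm")


def differential_attenuations(
    series: MeasurementSeries, include_baseline: bool = False
) -> list[AttenuationSpectrum]:
    """Differential attenuations ln(I) - ln(I_baseline), one per non-baseline record.

    Time series difference against the baseline time point; spatial cubes
    against the baseline pixel (row-major pixel order). With
    `include_baseline=True` the baseline's own all-zero record is kept.
    """
    if series.has_references:
        raise ValueError("series still carries raw references; call normalize_raw first")
    baseline = series.baseline_spectrum()
    _check_positive(baseline, series.grid, "baseline")
    log_base = np.log(baseline)
    out: list[AttenuationSpectrum] = []
    if series.mode == TIME_SERIES:
        _check_positive(series.spectra, series.grid, "time")
        for t in range(series.spectra.shape[0]):
            if t == series.baseline_index and not include_baseline:
                continue
            out.append(
                AttenuationSpectrum(grid=series.grid, delta_A=np.log(series.spectra[t]) - log_base)
            )
    else:
        _check_positive(series.spectra, series.grid, "pixel")
        H, W, _ = series.spectra.shape
        for r in range(H):
            for c in range(W):
                if (r, c) == series.baseline_index and not include_baseline:
                    continue
                out.append(
                    AttenuationSpectrum(
                        grid=series.grid, delta_A=np.log(series.spectra[r, c]) - log_base
                    )
                )
    return out


def spatial_delta_cube(series: MeasurementSeries) -> np.ndarray:
    """(H, W, L) array of per-pixel differential attenuations vs the baseline pixel."""
    if series.mode != SPATIAL_CUBE:
        raise ValueError("spatial_delta_cube requires a spatial_cube series")
    if series.has_references:
        raise ValueError("series still carries raw references; call normalize_raw first")
    _check_positive(series.spectra, series.grid, "pixel")
    return np.log(series.spectra) - np.log(series.baseline_spectrum())


def sample_strategy_a(
    ranges: SamplingRanges,
    basis: ChromophoreBasis,
    n: int,
    model_variant: Literal["linear", "scattering"] = "linear",
    seed: int | None = 0,
    pathlength_l: float = 1.0,
) -> TrainingSet:
    """Strategy (a): uniform parameter draws pushed through the forward model.

    Inputs are exact forward-model evaluations of the stored targets (the
    same code path as `forward_delta_attenuation`), so pushing any record's
    target back through the forward model reproduces its input bit for bit.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 samples, got {n}")
    needed = list(basis.names) + (list(SCATTER_PARAM_NAMES) if model_variant == "scattering" else [])
    ranges.require(needed)
    rng = np.random.default_rng(seed)
    targets = np.column_stack(
        [rng.uniform(*ranges[name], size=n) for name in basis.names]
    )
    scatter = None
    if model_variant == "scattering":
        scatter = np.column_stack([rng.uniform(*ranges[p], size=n) for p in SCATTER_PARAM_NAMES])
    inputs = np.empty((n, len(basis.grid)))
    for i in range(n):
        comp = DeltaComposition(
            delta_c=dict(zip(basis.names, targets[i].tolist())),
            scatter_before=ScatteringParams(s=scatter[i, 0], b=scatter[i, 1]) if scatter is not None else None,
            scatter_after=ScatteringParams(s=scatter[i, 2], b=scatter[i, 3]) if scatter is not None else None,
            pathlength_l=pathlength_l,
        )
        inputs[i] = forward_delta_attenuation(comp, basis).delta_A
    return TrainingSet(
        inputs=inputs,
        targets=targets,
        grid=basis.grid,
        names=basis.names,
        provenance="strategy_a",
        seed=seed,
        scatter_params=scatter,
    )


def build_strategy_b(
    series: MeasurementSeries | Sequence[AttenuationSpectrum],
    basis: ChromophoreBasis,
    config: SolveConfig | None = None,
) -> TrainingSet:
    """Strategy (b): pair each measured spectrum with its least-squares fit.

    Accepts a normalised measurement series (differenced against its baseline)
    or a ready list of differential attenuations. Non-converged fits are
    excluded and counted in the log; targets are, by construction, exactly the
    solver's outputs on the retained spectra.
    """
    config = config or SolveConfig(model_variant="linear")
    if isinstance(series, MeasurementSeries):
        spectra = differential_attenuations(series)
    else:
        spectra = list(series)
    if not spectra:
        raise ValueError("no non-baseline spectra to fit")
    fits = solve_batch(spectra, basis, config)
    kept = [(s, f) for s, f in zip(spectra, fits) if f.converged]
    dropped = len(fits) - len(kept)
    if dropped:
        logger.warning("strategy (b): excluded %d non-converged fits of %d", dropped, len(fits))
    if not kept:
        raise ValueError("all least-squares fits failed to converge; no training pairs")
    inputs = np.vstack([s.delta_A for s, _ in kept])
    targets = np.vstack([f.delta_c_vector(basis.names) for _, f in kept])
    scatter = None
    if config.model_variant == "scattering":
        scatter = np.array(
            [
                [f.composition.scatter_before.s, f.composition.scatter_before.b,
                 f.composition.scatter_after.s, f.composition.scatter_after.b]
                for _, f in kept
            ]
        )
    return TrainingSet(
        inputs=inputs,
        targets=targets,
        grid=basis.grid,
        names=basis.names,
        provenance="strategy_b",
        seed=None,
        scatter_params=scatter,
    )


def derive_ranges_from_fits(
    fits: Sequence[FitResult], names: Sequence[str], epsilon: float = 1e-6
) -> SamplingRanges:
    """Empirical per-parameter (min, max) over converged fits.

    This is the sampling convention when no physiological ranges are assumed:
    the extrema of the parameters found during optimisation define the ranges.
    Degenerate ranges (min == max) are widened by +-epsilon with a warning.
    """
    converged = [f for f in fits if f.converged]
    if len(converged) < 2:
        raise ValueError(f"need at least 2 converged fits, got {len(converged)}")
    names = tuple(names)
    values: dict[str, list[float]] = {n: [] for n in names}
    has_scatter = all(f.composition.has_scattering for f in converged)
    if has_scatter:
        for p in SCATTER_PARAM_NAMES:
            values[p] = []
    for f in converged:
        for n in names:
            values[n].append(f.composition.delta_c[n])
        if has_scatter:
            sb, sa = f.composition.scatter_before, f.composition.scatter_after
            values["s1"].append(sb.s)
            values["b1"].append(sb.b)
            values["s2"].append(sa.s)
            values["b2"].append(sa.b)
    ranges: dict[str, tuple[float, float]] = {}
    for key, vals in values.items():
        lo, hi = float(min(vals)), float(max(vals))
        if lo == hi:
            logger.warning("parameter %r has degenerate range at %g; widening by %g", key, lo, epsilon)
            lo, hi = lo - epsilon, hi + epsilon
        ranges[key] = (lo, hi)
    return SamplingRanges(ranges)


# ---------------------------------------------------------------------------
# Pseudo-real data generation
# ---------------------------------------------------------------------------

#: Canonical signs of a hypoxic excursion per chromophore: oxygenation and
#: oxidised-CCO signals fall, deoxyhemoglobin rises. Unknown names alternate.
_EXCURSION_SIGN = {
    "HbO2": -1.0,
    "HHb": +1.0,
    "diffCCO": -1.0,
    "oxCCO": -1.0,
    "redCCO": +1.0,
    "water": +1.0,
    "fat": -1.0,
}

#: Planted spatial contrasts (fractions of each chromophore's bound width)
#: for the two tissue regions of the synthetic cube. Region 1 emulates
#: well-perfused parenchyma, region 2 a hyper-vascularised, metabolically
#: altered area; the vessel baseline region sits at zero by construction.
_REGION_FRACTIONS = {
    1: {"HbO2": 0.20, "HHb": 0.08, "diffCCO": 0.10, "oxCCO": 0.12, "redCCO": 0.04,
        "water": 0.10, "fat": 0.05},
    2: {"HbO2": 0.45, "HHb": 0.15, "diffCCO": -0.18, "oxCCO": -0.10, "redCCO": 0.16,
        "water": 0.25, "fat": -0.10},
}


@dataclass(frozen=True)
class PseudoRealSpec:
    """Shape, physics variant and noise of a pseudo-real acquisition.

    `noise_sigma` is the additive Gaussian sigma on normalised intensity;
    `noise_ramp` linearly scales sigma across the band (sigma at the red edge
    is (1 + noise_ramp) times sigma at the blue edge), emulating the
    wavelength-dependent SNR loss of hyperspectral instruments.
    """

    mode: Literal["time_series", "spatial_cube"] = TIME_SERIES
    n_timepoints: int = 400
    shape: tuple[int, int] = (32, 32)
    model_variant: Literal["linear", "scattering"] = "linear"
    noise_sigma: float = 0.0
    noise_ramp: float = 0.0
    with_references: bool = False
    excursion_fraction: float = 0.6
    pathlength_l: float = 1.0


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of a pseudo-real series (for recovery tests)."""

    names: tuple[str, ...]
    delta_c: np.ndarray  # (T, k) or (H, W, k)
    scatter_params: np.ndarray | None = None  # (..., 4): s1, b1, s2, b2
    region_labels: np.ndarray | None = None  # (H, W) ints; 0 = vessel/baseline


def _bound_width(name: str) -> float:
    from .solvers import DEFAULT_BOUNDS

    lo, hi = DEFAULT_BOUNDS.get(name, (-0.5, 0.5))
    return hi - lo


def _hypoxia_profile(t: np.ndarray) -> np.ndarray:
    """Smooth rise-plateau-recovery bump on [0, 1], zero at t=0."""
    g = np.zeros_like(t)
    rise = (t >= 0.15) & (t < 0.35)
    plateau = (t >= 0.35) & (t < 0.6)
    fall = (t >= 0.6) & (t < 0.85)
    g[rise] = np.sin(0.5 * np.pi * (t[rise] - 0.15) / 0.2) ** 2
    g[plateau] = 1.0
    g[fall] = np.cos(0.5 * np.pi * (t[fall] - 0.6) / 0.25) ** 2
    return g


def _baseline_intensity(grid: SpectralGrid) -> np.ndarray:
    lo, hi = grid.range
    x = (grid.wavelengths - lo) / (hi - lo)
    return 0.55 + 0.2 * np.sin(2.0 * np.pi * x) * np.exp(-x) + 0.1 * x


def _noise(rng: np.random.Generator, shape: tuple[int, ...], grid: SpectralGrid,
           sigma: float, ramp: float) -> np.ndarray:
    if sigma == 0.0:
        return np.zeros(shape)
    lo, hi = grid.range
    x = (grid.wavelengths - lo) / (hi - lo)
    sigma_wl = sigma * (1.0 + ramp * x)
    return rng.normal(0.0, 1.0, size=shape) * sigma_wl


def generate_pseudo_real(
    spec: PseudoRealSpec, basis: ChromophoreBasis, seed: int | None = 0
) -> tuple[MeasurementSeries, GroundTruth]:
    """Emulate an acquisition with known planted composition changes.

    Time mode plants hypoxia-like excursions of each concentration (plus a
    small smooth wander) against a t=0 baseline; spatial mode plants two
    tissue regions and a vessel strip containing the baseline pixel. The
    generated intensities follow the forward model exactly before noise is
    added, so the sigma=0 case closes the loop with the solvers to numerical
    precision.
    """
    rng = np.random.default_rng(seed)
    if spec.mode == TIME_SERIES:
        return _pseudo_real_time(spec, basis, rng)
    return _pseudo_real_cube(spec, basis, rng)


def _scatter_pair(rng: np.random.Generator) -> tuple[float, float]:
    """A modest baseline scattering state (weight cm^-1, power)."""
    return float(rng.uniform(5.0, 15.0)), float(rng.uniform(0.8, 1.5))


def _pseudo_real_time(
    spec: PseudoRealSpec, basis: ChromophoreBasis, rng: np.random.Generator
) -> tuple[MeasurementSeries, GroundTruth]:
    T = spec.n_timepoints
    if T < 2:
        raise ValueError("time series needs at least 2 time points")
    t = np.linspace(0.0, 1.0, T)
    g = _hypoxia_profile(t)
    k = basis.n_chromophores
    delta_c = np.zeros((T, k))
    for i, name in enumerate(basis.names):
        width = _bound_width(name)
        sign = _EXCURSION_SIGN.get(name, -1.0 if i % 2 == 0 else 1.0)
        amp = sign * spec.excursion_fraction * 0.5 * width * rng.uniform(0.5, 1.0)
        wander = sum(
            0.05 * abs(amp) * rng.uniform(0.3, 1.0) * np.sin(2.0 * np.pi * f * t)
            for f in (1.0, 2.0, 3.0)
        )
        delta_c[:, i] = amp * g + wander

    scatter = None
    if spec.model_variant == "scattering":
        s1, b1 = _scatter_pair(rng)
        ds = float(rng.uniform(0.5, 2.5)) * float(rng.choice([-1.0, 1.0]))
        db = float(rng.uniform(-0.15, 0.15))
        scatter = np.empty((T, 4))
        scatter[:, 0] = s1
        scatter[:, 1] = b1
        scatter[:, 2] = np.clip(s1 + ds * g, 0.0, None)
        scatter[:, 3] = np.clip(b1 + db * g, 0.0, None)

    N0 = _baseline_intensity(basis.grid)
    spectra = np.empty((T, len(basis.grid)))
    for i in range(T):
        comp = DeltaComposition(
            delta_c=dict(zip(basis.names, delta_c[i].tolist())),
            scatter_before=ScatteringParams(s=scatter[i, 0], b=scatter[i, 1]) if scatter is not None else None,
            scatter_after=ScatteringParams(s=scatter[i, 2], b=scatter[i, 3]) if scatter is not None else None,
            pathlength_l=spec.pathlength_l,
        )
        spectra[i] = N0 * np.exp(forward_delta_attenuation(comp, basis).delta_A)
    spectra = spectra + _noise(rng, spectra.shape, basis.grid, spec.noise_sigma, spec.noise_ramp)

    dark = white = None
    if spec.with_references:
        dark, white = _references(basis.grid)
        spectra = dark + spectra * (white - dark)
    series = MeasurementSeries(
        mode=TIME_SERIES,
        grid=basis.grid,
        spectra=spectra,
        baseline_index=0,
        dark_reference=dark,
        white_reference=white,
    )
    return series, GroundTruth(names=basis.names, delta_c=delta_c, scatter_params=scatter)


def _references(grid: SpectralGrid) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = grid.range
    x = (grid.wavelengths - lo) / (hi - lo)
    dark = 0.02 + 0.01 * np.sin(2.0 * np.pi * x)
    white = 1.1 + 0.1 * np.cos(np.pi * x)
    return dark, white


def _pseudo_real_cube(
    spec: PseudoRealSpec, basis: ChromophoreBasis, rng: np.random.Generator
) -> tuple[MeasurementSeries, GroundTruth]:
    H, W = spec.shape
    if H < 4 or W < 4:
        raise ValueError("cube needs at least 4x4 pixels")
    k = basis.n_chromophores
    labels = np.ones((H, W), dtype=int)
    labels[:, W // 2:] = 2
    # vessel strip through the middle rows of the left quarter; baseline inside it
    vr = slice(H // 2 - 1, H // 2 + 1)
    labels[vr, : W // 4] = 0
    baseline_pixel = (H // 2, W // 8)

    yy, xx = np.meshgrid(np.linspace(0, 1, H), np.linspace(0, 1, W), indexing="ij")
    modulation = 1.0 + 0.08 * np.sin(2.0 * np.pi * xx) * np.sin(2.0 * np.pi * yy)

    delta_c = np.zeros((H, W, k))
    for region, fracs in _REGION_FRACTIONS.items():
        mask = labels == region
        for i, name in enumerate(basis.names):
            frac = fracs.get(name, 0.1 if i % 2 == 0 else -0.05)
            delta_c[mask, i] = frac * 0.5 * _bound_width(name) * modulation[mask]

    scatter = None
    if spec.model_variant == "scattering":
        s1, b1 = _scatter_pair(rng)
        scatter = np.zeros((H, W, 4))
        scatter[..., 0] = s1
        scatter[..., 1] = b1
        ds = {0: 0.0, 1: 1.0, 2: 2.5}
        db = {0: 0.0, 1: 0.05, 2: 0.12}
        for region in (0, 1, 2):
            mask = labels == region
            scatter[mask, 2] = s1 + ds[region]
            scatter[mask, 3] = b1 + db[region]

    N0 = _baseline_intensity(basis.grid)
    spectra = np.empty((H, W, len(basis.grid)))
    for r in range(H):
        for c in range(W):
            comp = DeltaComposition(
                delta_c=dict(zip(basis.names, delta_c[r, c].tolist())),
                scatter_before=ScatteringParams(s=scatter[r, c, 0], b=scatter[r, c, 1]) if scatter is not None else None,
                scatter_after=ScatteringParams(s=scatter[r, c, 2], b=scatter[r, c, 3]) if scatter is not None else None,
                pathlength_l=spec.pathlength_l,
            )
            spectra[r, c] = N0 * np.exp(forward_delta_attenuation(comp, basis).delta_A)
    spectra = spectra + _noise(rng, spectra.shape, basis.grid, spec.noise_sigma, spec.noise_ramp)

    dark = white = None
    if spec.with_references:
        dark, white = _references(basis.grid)
        spectra = dark + spectra * (white - dark)
    series = MeasurementSeries(
        mode=SPATIAL_CUBE,
        grid=basis.grid,
        spectra=spectra,
        baseline_index=baseline_pixel,
        dark_reference=dark,
        white_reference=white,
    )
    truth = GroundTruth(
        names=basis.names, delta_c=delta_c, scatter_params=scatter, region_labels=labels
    )
    return series, truth


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------

def save_series(series: MeasurementSeries, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("wavelengths", data=series.grid.wavelengths)
        f.create_dataset("spectra", data=series.spectra)
        f.attrs["mode"] = series.mode
        f.attrs["baseline"] = (
            series.baseline_index if series.mode == TIME_SERIES else list(series.baseline_index)
        )
        if series.dark_reference is not None:
            f.create_dataset("dark", data=series.dark_reference)
        if series.white_reference is not None:
            f.create_dataset("white", data=series.white_reference)


def load_series(path: str | Path) -> MeasurementSeries:
    with h5py.File(path, "r") as f:
        mode = str(f.attrs["mode"])
        baseline = f.attrs["baseline"]
        baseline_index = int(baseline) if mode == TIME_SERIES else (int(baseline[0]), int(baseline[1]))
        return MeasurementSeries(
            mode=mode,  # type: ignore[arg-type]
            grid=SpectralGrid(f["wavelengths"][:]),
            spectra=f["spectra"][:],
            baseline_index=baseline_index,
            dark_reference=f["dark"][:] if "dark" in f else None,
            white_reference=f["white"][:] if "white" in f else None,
        )


def save_training_set(ts: TrainingSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=ts.inputs)
        f.create_dataset("targets", data=ts.targets)
        f.create_dataset("wavelengths", data=ts.grid.wavelengths)
        if ts.scatter_params is not None:
            f.create_dataset("scatter_params", data=ts.scatter_params)
        norm = ts.normalization
        assert norm is not None
        for key in ("input_mean", "input_scale", "target_mean", "target_scale"):
            f.create_dataset(f"normalization/{key}", data=getattr(norm, key))
        f.attrs["names"] = list(ts.names)
        f.attrs["provenance"] = ts.provenance
        f.attrs["seed"] = -1 if ts.seed is None else ts.seed


def load_training_set(path: str | Path) -> TrainingSet:
    with h5py.File(path, "r") as f:
        seed = int(f.attrs["seed"])
        norm = Normalization(
            input_mean=f["normalization/input_mean"][:],
            input_scale=f["normalization/input_scale"][:],
            target_mean=f["normalization/target_mean"][:],
            target_scale=f["normalization/target_scale"][:],
        )
        return TrainingSet(
            inputs=f["inputs"][:],
            targets=f["targets"][:],
            grid=SpectralGrid(f["wavelengths"][:]),
            names=tuple(str(n) for n in f.attrs["names"]),
            provenance=str(f.attrs["provenance"]),  # type: ignore[arg-type]
            seed=None if seed == -1 else seed,
            normalization=norm,
            scatter_params=f["scatter_params"][:] if "scatter_params" in f else None,
        )
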