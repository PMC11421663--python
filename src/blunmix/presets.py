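"""Acquisition-convention presets.

Two stock configurations are shipped:

* **bNIRS** (time-resolved transmission spectroscopy of the neonatal brain):
  fit range 740-900 nm, 244 wavelengths, chromophores {HbO2, HHb, diffCCO},
  baseline taken at the start of monitoring.
* **HSI** (intraoperative hyperspectral reflectance imaging): fit range
  530-750 nm, chromophores {HbO2, HHb, oxCCO, redCCO, water, fat}, baseline
  taken at a blood-vessel pixel and differencing done in space, not time.
"""

from __future__ import annotations

from typing import Sequence

from .basis import ChromophoreBasis, SpectralGrid, build_basis, synthetic_chromophore_set
from .datasets import SamplingRanges
from .solvers import DEFAULT_BOUNDS, SCATTER_PARAM_NAMES

__all__ = [
    "BNIRS_CHROMOPHORES",
    "BNIRS_BAND_NM",
    "BNIRS_N_WAVELENGTHS",
    "HSI_CHROMOPHORES",
    "HSI_BAND_NM",
    "bnirs_grid",
    "hsi_grid",
    "synthetic_basis",
    "sampling_ranges",
]

BNIRS_CHROMOPHORES: tuple[str, ...] = ("HbO2", "HHb", "diffCCO")
BNIRS_BAND_NM: tuple[float, float] = (740.0, 900.0)
BNIRS_N_WAVELENGTHS = 244

HSI_CHROMOPHORES: tuple[str, ...] = ("HbO2", "HHb", "oxCCO", "redCCO", "water", "fat")
HSI_BAND_NM: tuple[float, float] = (530.0, 750.0)


def bnirs_grid(n: int = BNIRS_N_WAVELENGTHS) -> SpectralGrid:
    """Uniform 740-900 nm grid (244 wavelengths by default)."""
    return SpectralGrid.linspace(*BNIRS_BAND_NM, n)


def hsi_grid(n: int = 120) -> SpectralGrid:
    """Uniform 530-750 nm grid."""
    return SpectralGrid.linspace(*HSI_BAND_NM, n)


def synthetic_basis(
    names: Sequence[str] | None = None, grid: SpectralGrid | None = None
) -> ChromophoreBasis:
    """Basis of synthetic chromophore spectra (bNIRS set/grid by default)."""
    names = tuple(names) if names is not None else BNIRS_CHROMOPHORES
    grid = grid if grid is not None else bnirs_grid()
    return build_basis(synthetic_chromophore_set(names), grid, names)


def sampling_ranges(
    names: Sequence[str] | None = None, model_variant: str = "linear"
) -> SamplingRanges:
    """Physiological uniform-sampling ranges for synthetic training data.

    Concentration ranges follow the stock bounds (hemoglobins +-0.5 mM cm^-1,
    cytochrome signals +-0.25, water/fat +-0.1 volume fraction); the
    scattering variant adds s in [0, 100] cm^-1 and b in [0, 5] for both the
    before and after state.
    """
    names = tuple(names) if names is not None else BNIRS_CHROMOPHORES
    ranges = {}
    for n in names:
        if n not in DEFAULT_BOUNDS:
            raise KeyError(f"no stock sampling range for chromophore {n!r}; supply one explicitly")
        ranges[n] = DEFAULT_BOUNDS[n]
    if model_variant == "scattering":
        for p in SCATTER_PARAM_NAMES:
            ranges[p] = DEFAULT_BOUNDS[p]
    elif model_variant != "linear":
        raise ValueError(f"unknown model_variant {model_variant!r}")
    return SamplingRanges(ranges)
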