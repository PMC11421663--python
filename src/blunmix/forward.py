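"""Differential modified Beer-Lambert law.

Two measured intensity spectra I_1 (baseline) and I_2 define the differential
attenuation dA(lambda) = ln I_2 - ln I_1.  Under the modified Beer-Lambert law
with constant pathlength l and negligible change of unmodelled effects,

    dA(lambda) = -l * [ sum_i dc_i * mu_a^i(lambda) + d(s*mu_s)(lambda) ],

where dc_i are chromophore concentration changes and the scattering term
follows the power law s * (lambda / 500 nm)^-b with the anisotropy factor
(g = 0.9) folded into s = s' / (1 - g).  Natural logarithm is used throughout;
a base-10 reading rescales every dc by ln 10 and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .basis import ChromophoreBasis, SpectralGrid

__all__ = [
    "ScatteringParams",
    "DeltaComposition",
    "AttenuationSpectrum",
    "scattering_mu",
    "delta_scattering",
    "forward_delta_attenuation",
]

REFERENCE_WAVELENGTH_NM = 500.0


@dataclass(frozen=True)
class ScatteringParams:
    """Power-law scattering state: s * (lambda/500 nm)^-b.

    `s` (cm^-1) is the scattering weight with anisotropy scaling included;
    `b` is the dimensionless scattering power.
    """

    s: float
    b: float

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"scattering weight s must be >= 0, got {self.s}")
        if self.b < 0:
            raise ValueError(f"scattering power b must be >= 0, got {self.b}")


@dataclass(frozen=True)
class DeltaComposition:
    """Concentration changes plus optional before/after scattering states.

    `delta_c` maps chromophore name to its concentration change (mM for molar
    chromophores, dimensionless fraction for volume-fraction ones). Scattering
    states must be given as a pair (both or neither).
    """

    delta_c: Mapping[str, float]
    scatter_before: ScatteringParams | None = None
    scatter_after: ScatteringParams | None = None
    pathlength_l: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_c", dict(self.delta_c))
        if (self.scatter_before is None) != (self.scatter_after is None):
            raise ValueError("scatter_before and scatter_after must both be set or both be None")
        if self.pathlength_l <= 0:
            raise ValueError(f"pathlength must be positive, got {self.pathlength_l}")

    @property
    def has_scattering(self) -> bool:
        return self.scatter_before is not None

    def vector(self, names: tuple[str, ...]) -> np.ndarray:
        """Concentration-change vector ordered like a basis' names."""
        missing = [n for n in names if n not in self.delta_c]
        if missing:
            raise ValueError(f"composition lacks chromophores {missing}")
        return np.array([self.delta_c[n] for n in names], dtype=float)


@dataclass(frozen=True)
class AttenuationSpectrum:
    """Differential attenuation dA(lambda) = ln I_2 - ln I_1 on a grid (unitless)."""

    grid: SpectralGrid
    delta_A: np.ndarray

    def __post_init__(self) -> None:
        da = np.asarray(self.delta_A, dtype=float)
        object.__setattr__(self, "delta_A", da)
        if da.shape != (len(self.grid),):
            raise ValueError(f"delta_A shape {da.shape} does not match grid length {len(self.grid)}")
        if not np.all(np.isfinite(da)):
            raise ValueError("delta_A contains non-finite values")

    def to_table(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"wavelength_nm": self.grid.wavelengths, "delta_A": self.delta_A}).to_csv(
            path, index=False
        )


def scattering_mu(grid: SpectralGrid, params: ScatteringParams) -> np.ndarray:
    """Evaluate s * (lambda / 500 nm)^-b on the grid."""
    wl = grid.wavelengths
    return params.s * (wl / REFERENCE_WAVELENGTH_NM) ** (-params.b)


def delta_scattering(
    grid: SpectralGrid, before: ScatteringParams, after: ScatteringParams
) -> np.ndarray:
    """Net scattering change: after-state curve minus before-state curve."""
    return scattering_mu(grid, after) - scattering_mu(grid, before)


def forward_delta_attenuation(
    comp: DeltaComposition, basis: ChromophoreBasis
) -> AttenuationSpectrum:
    """Differential attenuation predicted for a composition change.

    dA = -l * (basis @ dc + net_scattering); the scattering term is omitted
    when the composition carries no scattering states (linear model).
    """
    dc = comp.vector(basis.names)
    total = basis.matrix @ dc
    if comp.has_scattering:
        assert comp.scatter_before is not None and comp.scatter_after is not None
        total = total + delta_scattering(basis.grid, comp.scatter_before, comp.scatter_after)
    return AttenuationSpectrum(grid=basis.grid, delta_A=-comp.pathlength_l * total)
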