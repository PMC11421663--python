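"""Chromophore absorption spectra and the basis matrix for spectral unmixing.

Absorption coefficients are tabulated per wavelength (nm). Molar chromophores
(hemoglobins, cytochromes) carry units cm^-1 mM^-1 so that concentration
changes come out in mM (mM cm^-1 under the unit-pathlength convention);
volume-fraction chromophores (water, fat) carry cm^-1 and their "concentration"
is a dimensionless fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "UnitKind",
    "ChromophoreSpectrum",
    "SpectralGrid",
    "ChromophoreBasis",
    "load_spectrum_table",
    "resample_to_grid",
    "build_basis",
    "load_basis_manifest",
    "synthetic_chromophore",
    "synthetic_chromophore_set",
    "SYNTHETIC_CHROMOPHORES",
]

MOLAR = "molar"
VOLUME_FRACTION = "volume_fraction"
UnitKind = str
_UNIT_KINDS = (MOLAR, VOLUME_FRACTION)


def _as_float_array(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D sequence, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Tabulated absorption coefficient of one chromophore.

    Parameters
    ----------
    name
        Identifier, e.g. ``"HbO2"``, ``"HHb"``, ``"diffCCO"``, ``"water"``.
    wavelengths
        Strictly increasing wavelengths in nm.
    mu_a
        Non-negative absorption coefficients; cm^-1 mM^-1 for ``molar``
        chromophores, cm^-1 for ``volume_fraction`` ones.
    unit_kind
        Either ``"molar"`` or ``"volume_fraction"``.
    """

    name: str
    wavelengths: np.ndarray
    mu_a: np.ndarray
    unit_kind: UnitKind = MOLAR

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelengths)
        mu = _as_float_array(self.mu_a)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "mu_a", mu)
        if self.unit_kind not in _UNIT_KINDS:
            raise ValueError(f"unit_kind must be one of {_UNIT_KINDS}, got {self.unit_kind!r}")
        if wl.size < 2:
            raise ValueError(f"spectrum {self.name!r} needs at least 2 points, got {wl.size}")
        if mu.size != wl.size:
            raise ValueError(
                f"spectrum {self.name!r}: {mu.size} coefficients for {wl.size} wavelengths"
            )
        diffs = np.diff(wl)
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0))
            raise ValueError(
                f"spectrum {self.name!r}: wavelengths not strictly increasing at index {bad + 1} "
                f"({wl[bad]} -> {wl[bad + 1]} nm)"
            )
        if np.any(mu < 0):
            bad = int(np.argmax(mu < 0))
            raise ValueError(
                f"spectrum {self.name!r}: negative absorption coefficient {mu[bad]} "
                f"at {wl[bad]} nm"
            )

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def to_table(self, path: str | Path, sep: str = ",") -> None:
        """Write the spectrum as a two-column delimited text table."""
        df = pd.DataFrame({"wavelength_nm": self.wavelengths, self.name: self.mu_a})
        df.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class SpectralGrid:
    """A strictly increasing wavelength grid (nm) on which spectra live."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelengths)
        object.__setattr__(self, "wavelengths", wl)
        if wl.size == 0:
            raise ValueError("grid must contain at least one wavelength")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("grid wavelengths must be strictly increasing")
        if np.any(wl <= 0):
            raise ValueError("wavelengths must be positive")

    @classmethod
    def linspace(cls, lo_nm: float, hi_nm: float, n: int) -> "SpectralGrid":
        return cls(np.linspace(lo_nm, hi_nm, n))

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def band_mask(self, band: tuple[float, float] | None) -> np.ndarray:
        """Boolean mask of wavelengths inside the inclusive band (lo_nm, hi_nm)."""
        if band is None:
            return np.ones(len(self), dtype=bool)
        lo, hi = band
        if lo > hi:
            raise ValueError(f"band lower edge {lo} exceeds upper edge {hi}")
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise ValueError(f"band ({lo}, {hi}) nm contains no grid wavelengths")
        return mask


@dataclass(frozen=True)
class ChromophoreBasis:
    """Matrix of absorption coefficients, one column per chromophore."""

    grid: SpectralGrid
    names: tuple[str, ...]
    matrix: np.ndarray  # shape (len(grid), len(names))
    unit_kinds: tuple[UnitKind, ...] = field(default=())

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "names", tuple(self.names))
        if not self.unit_kinds:
            object.__setattr__(self, "unit_kinds", tuple(MOLAR for _ in self.names))
        else:
            object.__setattr__(self, "unit_kinds", tuple(self.unit_kinds))
        if mat.shape != (len(self.grid), len(self.names)):
            raise ValueError(
                f"basis matrix shape {mat.shape} does not match "
                f"(grid={len(self.grid)}, chromophores={len(self.names)})"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicated chromophore names in {self.names}")
        if len(self.unit_kinds) != len(self.names):
            raise ValueError("unit_kinds length must match names")

    @property
    def n_chromophores(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        try:
            idx = self.names.index(name)
        except ValueError:
            raise KeyError(f"chromophore {name!r} not in basis {self.names}") from None
        return self.matrix[:, idx]

    def restrict(self, band: tuple[float, float]) -> "ChromophoreBasis":
        """Basis restricted to an inclusive wavelength band."""
        mask = self.grid.band_mask(band)
        return build_basis_from_matrix(
            SpectralGrid(self.grid.wavelengths[mask]),
            self.names,
            self.matrix[mask],
            self.unit_kinds,
        )


def load_spectrum_table(
    path: str | Path, unit_kind: UnitKind = MOLAR, name: str | None = None
) -> ChromophoreSpectrum:
    """Read a two-column delimited text table (wavelength nm, coefficient).

    The delimiter is sniffed from the header (comma or tab). The column header
    names the chromophore unless `name` is given. Malformed rows, non-monotone
    wavelengths, duplicated wavelengths and negative coefficients are rejected
    with the offending line named.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        # round_trip parsing keeps read(write(x)) bit-identical to x
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: could not parse table: {exc}") from exc
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (wavelength_nm, coefficient), got {df.shape[1]}")
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 data rows, got {df.shape[0]}")
    for col in df.columns:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(f"{path}: non-numeric value {bad[col].iloc[0]!r} on line {bad.index[0] + 2}")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    mu = df.iloc[:, 1].to_numpy(dtype=float)
    dup = np.flatnonzero(np.diff(wl) == 0)
    if dup.size:
        raise ValueError(f"{path}: duplicated wavelength {wl[dup[0]]} nm on line {dup[0] + 3}")
    nonmono = np.flatnonzero(np.diff(wl) < 0)
    if nonmono.size:
        raise ValueError(
            f"{path}: wavelengths decrease ({wl[nonmono[0]]} -> {wl[nonmono[0] + 1]} nm) "
            f"on line {nonmono[0] + 3}"
        )
    neg = np.flatnonzero(mu < 0)
    if neg.size:
        raise ValueError(f"{path}: negative coefficient {mu[neg[0]]} on line {neg[0] + 2}")
    return ChromophoreSpectrum(
        name=name or str(df.columns[1]), wavelengths=wl, mu_a=mu, unit_kind=unit_kind
    )


def resample_to_grid(spectrum: ChromophoreSpectrum, grid: SpectralGrid) -> ChromophoreSpectrum:
    """Linearly interpolate a tabulated spectrum onto a grid (no extrapolation).

    Exact at wavelengths the table already contains.
    """
    lo, hi = spectrum.range
    glo, ghi = grid.range
    if glo < lo or ghi > hi:
        raise ValueError(
            f"grid range ({glo}, {ghi}) nm extends beyond spectrum {spectrum.name!r} "
            f"tabulated range ({lo}, {hi}) nm; extrapolation is not performed"
        )
    mu = np.interp(grid.wavelengths, spectrum.wavelengths, spectrum.mu_a)
    return ChromophoreSpectrum(
        name=spectrum.name, wavelengths=grid.wavelengths, mu_a=mu, unit_kind=spectrum.unit_kind
    )


def build_basis(
    spectra: Sequence[ChromophoreSpectrum],
    grid: SpectralGrid,
    names: Sequence[str] | None = None,
) -> ChromophoreBasis:
    """Resample spectra onto `grid` and assemble the basis matrix.

    Columns follow `names` order (default: order of `spectra`). A rank check
    rejects bases that cannot be solved on the chosen grid.
    """
    by_name = {s.name: s for s in spectra}
    if len(by_name) != len(spectra):
        seen: set[str] = set()
        for s in spectra:
            if s.name in seen:
                raise ValueError(f"duplicated chromophore name {s.name!r}")
            seen.add(s.name)
    ordered = list(names) if names is not None else [s.name for s in spectra]
    missing = [n for n in ordered if n not in by_name]
    if missing:
        raise ValueError(f"requested chromophores not provided: {missing}")
    if len(set(ordered)) != len(ordered):
        raise ValueError(f"duplicated chromophore names requested: {ordered}")
    cols = [resample_to_grid(by_name[n], grid).mu_a for n in ordered]
    matrix = np.column_stack(cols)
    kinds = tuple(by_name[n].unit_kind for n in ordered)
    return build_basis_from_matrix(grid, ordered, matrix, kinds)


def build_basis_from_matrix(
    grid: SpectralGrid,
    names: Sequence[str],
    matrix: np.ndarray,
    unit_kinds: Sequence[UnitKind] | None = None,
) -> ChromophoreBasis:
    basis = ChromophoreBasis(
        grid=grid,
        names=tuple(names),
        matrix=matrix,
        unit_kinds=tuple(unit_kinds) if unit_kinds else (),
    )
    rank = np.linalg.matrix_rank(basis.matrix)
    if rank < basis.n_chromophores:
        raise ValueError(
            f"chromophore basis is rank-deficient on this grid "
            f"(rank {rank} < {basis.n_chromophores}); widen the wavelength range or "
            f"drop a collinear chromophore"
        )
    return basis


def load_basis_manifest(path: str | Path, grid: SpectralGrid) -> ChromophoreBasis:
    """Build a basis from a YAML manifest mapping name -> {path, unit_kind}.

    Paths are resolved relative to the manifest file. Chromophore order in the
    manifest is preserved.
    """
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or not manifest:
        raise ValueError(f"{path}: manifest must be a non-empty mapping of chromophore entries")
    spectra = []
    for cname, entry in manifest.items():
        table = path.parent / entry["path"]
        kind = entry.get("unit_kind", MOLAR)
        spectra.append(load_spectrum_table(table, unit_kind=kind, name=cname))
    return build_basis(spectra, grid)


# ---------------------------------------------------------------------------
# Synthetic chromophores for tests and demonstrations.
#
# Real extinction compilations are user-supplied inputs; these smooth
# deterministic stand-ins (hemoglobin-like double peaks, Gaussian bumps for
# the cytochromes, long-wavelength ramps for water and fat) share the real
# tables' qualitative structure and are linearly independent on any grid that
# spans a few of their features.
# ---------------------------------------------------------------------------

def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - center) / width) ** 2))


_SYNTHETIC_SHAPES: dict[str, tuple[UnitKind, tuple[tuple[float, float, float], ...], float]] = {
    # name: (unit_kind, ((amplitude, center_nm, width_nm), ...), floor)
    "HbO2": (MOLAR, ((2.0, 560.0, 25.0), (1.2, 900.0, 80.0)), 0.30),
    "HHb": (MOLAR, ((2.2, 555.0, 30.0), (1.0, 760.0, 30.0)), 0.25),
    "diffCCO": (MOLAR, ((0.9, 620.0, 45.0), (0.7, 830.0, 55.0)), 0.05),
    "oxCCO": (MOLAR, ((1.5, 605.0, 40.0), (0.8, 830.0, 60.0)), 0.10),
    "redCCO": (MOLAR, ((1.6, 640.0, 35.0), (0.5, 780.0, 45.0)), 0.12),
    "water": (VOLUME_FRACTION, ((0.6, 970.0, 45.0), (0.15, 740.0, 60.0)), 0.05),
    "fat": (VOLUME_FRACTION, ((0.5, 930.0, 40.0), (0.12, 690.0, 50.0)), 0.04),
}

SYNTHETIC_CHROMOPHORES = tuple(_SYNTHETIC_SHAPES)


def synthetic_chromophore(
    name: str, lo_nm: float = 400.0, hi_nm: float = 1000.0, n_points: int = 601
) -> ChromophoreSpectrum:
    """Deterministic synthetic absorption spectrum (test fixture, not literature data)."""
    if name not in _SYNTHETIC_SHAPES:
        raise KeyError(f"no synthetic shape for {name!r}; choose from {SYNTHETIC_CHROMOPHORES}")
    kind, bumps, floor = _SYNTHETIC_SHAPES[name]
    wl = np.linspace(lo_nm, hi_nm, n_points)
    mu = np.full_like(wl, floor)
    for amp, center, width in bumps:
        mu = mu + amp * _gauss(wl, center, width)
    return ChromophoreSpectrum(name=name, wavelengths=wl, mu_a=mu, unit_kind=kind)


def synthetic_chromophore_set(
    names: Sequence[str], lo_nm: float = 400.0, hi_nm: float = 1000.0, n_points: int = 601
) -> list[ChromophoreSpectrum]:
    return [synthetic_chromophore(n, lo_nm, hi_nm, n_points) for n in names]
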