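import numpy as np
import pytest

from blunmix.basis import SpectralGrid, build_basis, synthetic_chromophore_set
from blunmix.presets import BNIRS_CHROMOPHORES, HSI_CHROMOPHORES


@pytest.fixture(scope="session")
def nirs_grid_small() -> SpectralGrid:
    """Coarse 740-900 nm grid for fast unit tests."""
    return SpectralGrid.linspace(740.0, 900.0, 60)


@pytest.fixture(scope="session")
def nirs_basis_small(nirs_grid_small):
    """3-chromophore basis (HbO2, HHb, diffCCO) on the coarse NIR grid."""
    return build_basis(
        synthetic_chromophore_set(BNIRS_CHROMOPHORES), nirs_grid_small, BNIRS_CHROMOPHORES
    )


@pytest.fixture(scope="session")
def hsi_grid_small() -> SpectralGrid:
    return SpectralGrid.linspace(530.0, 750.0, 48)


@pytest.fixture(scope="session")
def hsi_basis_small(hsi_grid_small):
    """6-chromophore basis on the coarse visible/NIR grid."""
    return build_basis(
        synthetic_chromophore_set(HSI_CHROMOPHORES), hsi_grid_small, HSI_CHROMOPHORES
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
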