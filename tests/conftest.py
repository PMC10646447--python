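import numpy as np
import pytest

from islandtone import synthetic
from islandtone.spectra import IrradianceSpectrum, ReflectanceSpectrum, WavelengthGrid


@pytest.fixture(scope="session")
def sun():
    return synthetic.gen_solar_spectrum()


@pytest.fixture(scope="session")
def full_grid():
    return WavelengthGrid()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return WavelengthGrid(400, 700, 10)


def make_spectrum(grid, values, **meta):
    meta.setdefault("specimen_id", "s1")
    meta.setdefault("surface", "dorsal")
    return ReflectanceSpectrum(grid=grid, values=np.asarray(values, dtype=float), **meta)


@pytest.fixture
def flat_sun(small_grid):
    return IrradianceSpectrum(grid=small_grid, intensity=np.ones(len(small_grid)))
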