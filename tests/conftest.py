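import numpy as np
import pytest

from hddot.arrays import default_cap_layout, default_tile
from hddot.forward import OpticalProperties
from hddot.mesh import orient_head
from hddot.phantoms import make_phantom


@pytest.fixture(scope="session")
def cap_layout():
    return default_cap_layout()


@pytest.fixture(scope="session")
def tile():
    return default_tile()


@pytest.fixture(scope="session")
def hemisphere():
    """Coarse oriented hemisphere phantom shared across geometry tests."""
    return orient_head(make_phantom("hemisphere", resolution=7.0))


@pytest.fixture(scope="session")
def hemisphere_scalp(hemisphere):
    return hemisphere.scalp_surface()


@pytest.fixture(scope="session")
def small_slab():
    """Tiny slab for FEM unit tests (a few hundred nodes)."""
    return make_phantom("slab", layers=(7.0, 2.0, 4.0), resolution=5.0,
                        size=(40.0, 40.0, 25.0))


def homogeneous_properties(mua: float, musp: float, wavelengths=(735.0, 850.0),
                           n: float = 1.4) -> OpticalProperties:
    tissues = ("ECT", "CSF", "GM", "WM")
    return OpticalProperties(
        mua={t: {wl: mua for wl in wavelengths} for t in tissues},
        musp={t: {wl: musp for wl in wavelengths} for t in tissues},
        n=n,
    )
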