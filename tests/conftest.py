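import numpy as np
import pytest

from isosim import TissueParams, make_sphere_phantom, make_uniform_phantom


@pytest.fixture
def gel_tissue():
    return TissueParams("gel", rho=1.0, t1=0.6, t2=0.08)


@pytest.fixture
def short_t2_tissue():
    """Tendon-like short-T2 tissue, inside the signal-equation regime TE << T1."""
    return TissueParams("tendon", rho=1.0, t1=0.6, t2=0.012)


@pytest.fixture
def small_sphere_phantom(gel_tissue):
    """16x16 single-slice sphere with fuzzy (supersampled) boundary."""
    return make_sphere_phantom(
        (16, 16, 1), 1e-3, center=(7.5, 7.5, 0), radius=4, tissue=gel_tissue,
        supersample=2,
    )


@pytest.fixture
def uniform_cube(short_t2_tissue):
    return make_uniform_phantom((8, 8, 8), 1e-3, [short_t2_tissue], [1.0])


def intensity_centroid(mag: np.ndarray) -> tuple:
    """Intensity-weighted centroid of a magnitude image, voxel units."""
    w = mag / mag.sum()
    out = []
    for ax in range(mag.ndim):
        other = tuple(a for a in range(mag.ndim) if a != ax)
        out.append(float((w.sum(axis=other) * np.arange(mag.shape[ax])).sum()))
    return tuple(out)
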