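import numpy as np
import pytest

from dynloc import hrtf as hrtf_mod
from dynloc import simulate


@pytest.fixture(scope="session")
def sparse_set():
    """91-direction synthetic HRTF set shared across tests."""
    return simulate.make_synthetic_hrtf(seed=7)


@pytest.fixture(scope="session")
def dense_set(sparse_set):
    """One-subdivision dense interpolation of the synthetic set."""
    mesh = hrtf_mod.subdivide(
        hrtf_mod.triangulate(sparse_set.az_deg, sparse_set.el_deg), 1
    )
    az, el = hrtf_mod.mesh_directions(mesh)
    return hrtf_mod.interpolate_to_dense(sparse_set, az, el)


@pytest.fixture(scope="session")
def icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    from dynloc.coords import unit_to_sph

    az, el = unit_to_sph(v[:, 0], v[:, 1], v[:, 2])
    return hrtf_mod.triangulate(az, el)


def db_mag(ir):
    mag = np.abs(np.fft.fft(ir, axis=-1))
    return 20.0 * np.log10(np.maximum(mag, 1e-300))
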