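import numpy as np
import pytest

import melanophot as mp


@pytest.fixture(scope="session")
def obs():
    return mp.default_observer()


@pytest.fixture(scope="session")
def device():
    return mp.example_device()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def cofactor_inverse_3x3(m):
    """Explicit adjugate/determinant inverse of a 3x3 matrix (oracle)."""
    m = np.asarray(m, dtype=float)
    det = (
        m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
        - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
        + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0])
    )
    cof = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            minor = np.delete(np.delete(m, i, axis=0), j, axis=1)
            cof[i, j] = (-1) ** (i + j) * (
                minor[0, 0] * minor[1, 1] - minor[0, 1] * minor[1, 0]
            )
    return cof.T / det


def random_toy_device(rng, n_primaries=3):
    """Random full-rank Gaussian-primary device on the canonical grid."""
    prims, labels = [], []
    for i in range(n_primaries):
        peak = rng.uniform(420.0, 650.0)
        fwhm = rng.uniform(15.0, 60.0)
        prims.append(mp.gaussian_primary(peak, fwhm, rng.uniform(0.5e-2, 2e-2)))
        labels.append(f"p{i}@{peak:.0f}")
    return mp.MultiprimaryDevice(primaries=tuple(prims), labels=tuple(labels))
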