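import numpy as np
import pytest

from napvc.core import RelaxationTimes, SequenceParams


@pytest.fixture(scope="session")
def params() -> SequenceParams:
    """Default acquisition: TR/TE 15/0.1 ms, 5 ms readout, 2 mm nominal."""
    return SequenceParams()


@pytest.fixture(scope="session")
def mid_relax() -> RelaxationTimes:
    """Relaxation times of the mid-portion tendon tissue."""
    return RelaxationTimes(t1=19.2, t2l_star=14.2, t2s_star=1.4, short_fraction=0.6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def gaussian_kernel(halfwidth: int, sigma: float, voxel_size: float = 1.0):
    """Unit-sum isotropic Gaussian kernel used as a stand-in PSF in tests."""
    from napvc.psf import PSFKernel

    ax = np.arange(-halfwidth, halfwidth + 1, dtype=float)
    g1 = np.exp(-0.5 * (ax / sigma) ** 2)
    k = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    return PSFKernel(k / k.sum(), voxel_size=voxel_size)
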