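import numpy as np
import pytest

from thalparc import odf, phantom


@pytest.fixture(scope="session")
def scheme():
    """Default single-shell scheme: 1 b=0 + 64 directions at b=1000."""
    return phantom.default_scheme()


@pytest.fixture(scope="session")
def basis6(scheme):
    """Order-6 SH basis on the default shell directions."""
    return odf.build_sh_basis(6, scheme.directions)


@pytest.fixture(scope="session")
def transform6():
    return odf.CSATransform(6)


@pytest.fixture(scope="session")
def quad():
    """Dense spherical quadrature (points, weights summing to 4*pi)."""
    return odf.sphere_quadrature(48, 96)


@pytest.fixture(scope="session")
def clean_phantom():
    """Default-geometry phantom without contamination rims, SNR 30, seed 1."""
    spec = phantom.PhantomSpec(csf_rim_mm=0.0, capsule_rim_mm=0.0)
    dwi, mask, csf, truth = phantom.generate_phantom(spec, seed=1)
    return spec, dwi, mask, csf, truth


@pytest.fixture(scope="session")
def noisefree_phantom():
    spec = phantom.PhantomSpec(snr=None)
    dwi, mask, csf, truth = phantom.generate_phantom(spec, seed=0)
    return spec, dwi, mask, csf, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
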