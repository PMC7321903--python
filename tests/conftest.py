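import numpy as np
import pytest

from retinotract import (
    PhantomSpec,
    build_phantom,
    fit_tensor,
    tensor_scalars,
)


@pytest.fixture(scope="session")
def phantom():
    """The default synthetic study (seed 42, 2 x 200 labelled streamlines)."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def fitted(phantom):
    """Tensor field fit on the phantom's noisy signal, plus scalar maps."""
    field = fit_tensor(phantom.dwi, phantom.gtab, phantom.wm_mask)
    return field, tensor_scalars(field)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """A quieter, smaller phantom for analytic comparisons."""
    spec = PhantomSpec(n_streamlines_per_bundle=40, snr=1e9, rng_seed=3)
    return build_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
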