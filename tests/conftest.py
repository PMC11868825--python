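import numpy as np
import pytest

import qdi


@pytest.fixture(scope="session")
def ds1_scheme():
    return qdi.make_scheme("dataset1", seed=1)


@pytest.fixture(scope="session")
def ds1_short_scheme():
    return qdi.make_scheme("dataset1_short", seed=1)


@pytest.fixture(scope="session")
def ds3_scheme():
    return qdi.make_scheme("dataset3", seed=1)


@pytest.fixture(scope="session")
def gm_params():
    # representative grey-matter exemplar used throughout
    return qdi.QDIParams(d12=0.8e-3, alpha=0.88)


@pytest.fixture(scope="session")
def small_ip_table():
    return qdi.build_ip_table(d12_range=(2e-4, 3e-3), alpha_range=(0.5, 0.95),
                              n_d12=12, n_alpha=12)


def noiseless_curve(scheme, params, s0=1000.0):
    """Synthesize one voxel's powder-averaged curve from the forward model."""
    signal = s0 * np.atleast_1d(qdi.qdi_attenuation(scheme.bvals, params))
    curves = qdi.powder_average(signal[None, :], scheme)
    return curves.curve(0)
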