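import numpy as np
import pytest

import cvrkit as ck


@pytest.fixture(scope="session")
def paradigm():
    return ck.Paradigm()


@pytest.fixture(scope="session")
def acq():
    return ck.AcquisitionParams()


@pytest.fixture(scope="session")
def phantom():
    return ck.make_phantom(grid_shape=(16, 16, 16), seed=0)


@pytest.fixture(scope="session")
def noiseless_trace(paradigm):
    return ck.make_capno_trace(paradigm, bh_rise=8.0, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def regressor(noiseless_trace, acq):
    return ck.build_regressor(noiseless_trace, acq)
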