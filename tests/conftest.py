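import numpy as np
import pytest

from nmjquant import GroundTruth, Protocol, QuantalKernel


@pytest.fixture
def truth():
    """Default ground truth used across tests."""
    return GroundTruth()


@pytest.fixture
def clean_truth():
    """Deterministic-amplitude ground truth: no quantal, NMJ or noise variability."""
    return GroundTruth(q_cv=0.0, noise_sd=0.0, nmj_cv=0.0)


@pytest.fixture
def kernel():
    return QuantalKernel()


@pytest.fixture
def vm_protocols():
    return [Protocol.low_freq_evoked(ca_mm=c, n_stim=20) for c in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
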