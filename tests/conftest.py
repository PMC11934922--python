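import numpy as np
import pytest

from probefold.benchmark import recovery_benchmark


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def recovery_results():
    """20-seed multi-condition recovery benchmark, shared by the probing- and
    alignment-integration acceptance checks."""
    return recovery_benchmark(range(20), n_samples=500, noise_sigma=0.3, with_msa=True)
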