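import numpy as np
import pytest

from g4reg import synth as sy


@pytest.fixture(scope="session")
def default_truth():
    """One default synthetic world shared by read-only tests."""
    return sy.synth_genome_and_genes(sy.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def default_peaks(default_truth):
    return sy.synth_g4_peaks(default_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
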