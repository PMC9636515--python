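import numpy as np
import pytest

import sigcca as sc


@pytest.fixture(scope="session")
def small_catalog_truth():
    """Simulated SBS-96 catalog with K=3 known signatures (shared across tests)."""
    return sc.simulate_catalog(M=96, N=50, K=3, mutations_per_sample=1000,
                               noise="multinomial", seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    """Two tiny contigs with engineered repeat/homopolymer structure."""
    return sc.ReferenceGenome({
        "chr1": "AACAAGTGCATTTTTTGACGT",
        "chr2": "TCACACATGTCTATCGGCAAAAC",
    })
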