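import numpy as np
import pytest

import qtlshrink as qs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest full-sib dataset on the 100-cM chromosome design."""
    genome, truth = qs.chromosome_design()
    ds, st = qs.simulate_dataset(genome, truth, 60, 6, rng_seed=42)
    return genome, truth, ds, st


@pytest.fixture(scope="session")
def tiny_map():
    """Three 6-allele markers on a 20-cM chromosome."""
    return qs.evenly_spaced_map(20.0, 3, n_alleles=6)
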