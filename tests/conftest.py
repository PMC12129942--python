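import numpy as np
import pytest

from cotodelim.datatypes import GenotypeMatrix, Site
from cotodelim.simulate import buxifolius_complex_fixture


@pytest.fixture(scope="session")
def fixture_data():
    return buxifolius_complex_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def genotypes_from_array(arr, chrom="chr1", missing_rate=0.0, rng=None):
    """Helper: wrap a dosage array as a GenotypeMatrix."""
    arr = np.asarray(arr, dtype=np.int16)
    if missing_rate and rng is not None:
        mask = rng.random(arr.shape) < missing_rate
        arr = np.where(mask, -9, arr)
    n, m = arr.shape
    samples = [f"s{i}" for i in range(n)]
    sites = [Site(chrom, j + 1) for j in range(m)]
    return GenotypeMatrix(samples, sites, arr)


@pytest.fixture
def genotype_factory():
    return genotypes_from_array
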