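import numpy as np
import pytest

from cghcnv.data_model_io import GenomeLayout, SegmentCall
from cghcnv.synthetic_data import default_layout, default_pedigree


@pytest.fixture
def layout():
    return default_layout(n_autosomes=3, autosome_length=10_000_000)


@pytest.fixture
def small_layout():
    return default_layout(n_autosomes=1, autosome_length=1_000_000)


@pytest.fixture
def pedigree():
    return default_pedigree(n_trios=3, n_extra=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_call(animal="A1", chrom="chr1", start=1000, length=5000,
              first_probe=10, datapoints=4, l2r=-0.6):
    return SegmentCall(animal=animal, chrom=chrom, start=start,
                       stop=start + length, first_probe=first_probe,
                       last_probe=first_probe + datapoints - 1,
                       l2r=l2r, datapoints=datapoints)


@pytest.fixture
def call_factory():
    return make_call
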