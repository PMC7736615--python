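import numpy as np
import pytest
from hypothesis import settings

from csopred import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from csopred.dataio import ProteinRecord, SiteAnnotation


@pytest.fixture
def tiny_proteins():
    return [
        ProteinRecord("p1", "ACDC"),
        ProteinRecord("p2", "CACC"),
        ProteinRecord("p3", "MKLVNQ"),  # no cysteine
    ]


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions (~500 pos / 2500 neg)."""
    spec = synthetic.SyntheticSpec(seed=1)
    pos, neg = synthetic.generate_segments(spec)
    return spec, pos, neg


@pytest.fixture(scope="session")
def small_dataset():
    """A down-scaled synthetic dataset for fast unit tests."""
    spec = synthetic.SyntheticSpec(n_proteins=120, seed=7)
    pos, neg = synthetic.generate_segments(spec)
    return spec, pos, neg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
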