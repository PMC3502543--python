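import numpy as np
import pytest

from crosspeak.genomic_io import GenomeLayout, SampleMeta


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 10_000_000, "chr2": 10_000_000}, assembly="synth1")


@pytest.fixture
def toy_samples():
    """3 human + 2 chimpanzee neuronal samples, uniform libraries."""
    return [
        SampleMeta("H1", "human", "NeuN+", 10_000_000),
        SampleMeta("H2", "human", "NeuN+", 10_000_000),
        SampleMeta("H3", "human", "NeuN+", 10_000_000),
        SampleMeta("C1", "chimpanzee", "NeuN+", 10_000_000),
        SampleMeta("C2", "chimpanzee", "NeuN+", 10_000_000),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)

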