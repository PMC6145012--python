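import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the brute-force oracle module

from strtool import PipelineConfig, example_loci


@pytest.fixture(scope="session")
def loci8():
    """The synthetic eight-locus tetranucleotide panel."""
    return example_loci()


@pytest.fixture(scope="session")
def locus_a(loci8):
    return loci8["A"]


@pytest.fixture()
def cfg():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
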