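import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mmphylo import Alignment, read_tree
from mmphylo.benchmarks import random_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def four_taxon_tree():
    return read_tree("((A:0.12,B:0.23):0.08,(C:0.31,D:0.05):0.14);")


@pytest.fixture
def three_taxon_tree():
    return read_tree("((A:0.1,B:0.1):0.05,C:0.2);")


@pytest.fixture
def small_alignment():
    return Alignment(["A", "B", "C", "D"], ["ACGT", "ACGA", "ACTA", "GCTA"])


def make_random_specs(n, seed, **kwargs):
    rng = np.random.default_rng(seed)
    return [random_spec(rng, **kwargs) for _ in range(n)]
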