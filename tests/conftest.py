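import numpy as np
import pytest

from orsel.treeio import parse_newick


@pytest.fixture
def species_abc():
    """Species tree ((A,B),C) with unit-ish branch lengths."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    """Ultrametric 4-taxon species tree ((A,B),(C,D))."""
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
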