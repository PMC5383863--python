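import numpy as np
import pytest

from pggalloc import netgen
from pggalloc.game import GameParams


@pytest.fixture
def triangle():
    return netgen.make_complete(3)


@pytest.fixture
def wheel5():
    return netgen.make_wheel(5)


@pytest.fixture
def ring6():
    return netgen.make_ring(6)


@pytest.fixture
def small_ucm():
    """A modest scale-free substrate shared by engine-level tests."""
    ds = netgen.sample_powerlaw_degree_sequence(300, 2.5, 2, 17, seed=42)
    return netgen.build_ucm_graph(ds, seed=42)


@pytest.fixture
def default_params():
    return GameParams(r=4.0, c=1.0, alpha=2.0)
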