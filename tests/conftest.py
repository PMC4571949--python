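import dendropy
import numpy as np
import pytest

from rhodofit import default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(20150720)


def seven_taxon_tree() -> dendropy.Tree:
    """Deeply diverged 7-leaf tree: internal branches >= 0.3, terminals 0.1."""
    newick = (
        "(((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3):0.3,"
        "((E:0.1,F:0.1):0.3,G:0.1):0.3):0.0;"
    )
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture()
def clean_tree():
    return seven_taxon_tree()
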