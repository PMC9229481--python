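import dendropy
import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20220913)


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted",
        taxon_namespace=dendropy.TaxonNamespace(),
    )


@pytest.fixture
def cherry():
    """Two tips, both branches length 1."""
    return tree_from_newick("(A:1,B:1);")


@pytest.fixture
def four_tip_tree():
    return tree_from_newick("((A:0.5,B:0.8):0.3,(C:1.2,D:0.4):0.6);")
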