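import numpy as np
import pytest

from rcclock.alignment import ProteinAlignment
from rcclock.timetree import Node, TimeTree


def make_tree(newick_like=None):
    """The standard 4-tip test chronogram ((A,B),(C,D)) with ages in Ga."""
    a, b, c, d = (Node(x, age=0.0) for x in "ABCD")
    ab = Node(age=1.0)
    ab.add_child(a)
    ab.add_child(b)
    cd = Node(age=1.5)
    cd.add_child(c)
    cd.add_child(d)
    root = Node(age=2.0)
    root.add_child(ab)
    root.add_child(cd)
    return TimeTree(root)


@pytest.fixture
def quartet_tree():
    return make_tree()


@pytest.fixture
def quartet_tree_rated():
    tree = make_tree()
    for node in tree.nodes:
        node.rate = 0.3
    return tree


@pytest.fixture
def two_tip_tree():
    a, b = Node("A", age=0.0, rate=1.0), Node("B", age=0.0, rate=1.0)
    root = Node(age=0.25, rate=1.0)
    root.add_child(a)
    root.add_child(b)
    return TimeTree(root)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_alignment(ids, n_sites, rng):
    from rcclock.alignment import AMINO_ACIDS

    rows = tuple(
        "".join(rng.choice(list(AMINO_ACIDS), size=n_sites)) for _ in ids
    )
    return ProteinAlignment(tuple(ids), rows)
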