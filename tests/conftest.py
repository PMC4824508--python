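import pytest

from phylobeta import parse_newick
from phylobeta.fixtures import small_tree_suite


@pytest.fixture
def t2():
    """Two tips with unequal branch lengths; the smallest possible tree."""
    return parse_newick("(x:2,y:3);")


@pytest.fixture
def t3():
    """Three tips, one cherry: the worked micro-example tree."""
    return parse_newick("((x:1,y:1):1,z:1);")


@pytest.fixture
def balanced4():
    return parse_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture(scope="session")
def suite():
    """The small-tree suite: all shapes at 2-7 tips, plus a multifurcating
    tree and one with unequal branch lengths."""
    return small_tree_suite()
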