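import pytest

from spacerorient.arrays import ArrayGroup, SpacerArray
from spacerorient.trees import read_newick


def make_group(group_id, specs):
    """specs: list of (array_id, spacer list)."""
    return ArrayGroup(group_id, [SpacerArray(aid, list(s)) for aid, s in specs])


@pytest.fixture
def nested_group():
    """Arrays related by pure polarized growth: each is a suffix of the next."""
    return make_group("nested", [("A", [1, 2, 3]), ("B", [2, 3]), ("C", [3])])


@pytest.fixture
def identical_group():
    return make_group("identical", [("A", [1, 2, 3]), ("B", [1, 2, 3])])


@pytest.fixture
def symmetric_group():
    """Presence structure invariant under simultaneous array reversal."""
    return make_group("symmetric", [("A", [1, 2, 3, 4, 5]), ("B", [1, 2, 4, 5])])


@pytest.fixture
def two_leaf_tree():
    return read_newick("(A:1.0,B:1.0);")


@pytest.fixture
def three_leaf_tree():
    return read_newick("((A:1.0,B:1.0):0.5,C:1.5);")
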