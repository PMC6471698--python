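import random

import pytest

from aspra import ScoreConfig, example_structure
from aspra.algebra import CONCAT_SYM, CROSS_SYM, NEST_SYM
from aspra.structural import HairpinLeaf, OperatorNode


@pytest.fixture
def knot_18mer():
    """18-mer with a concatenation, two nestings and one crossing."""
    return example_structure("pseudoknot_18mer")


@pytest.fixture
def knot_one():
    return example_structure("knot_one_crossing")


@pytest.fixture
def knot_two():
    return example_structure("knot_two_crossings")


@pytest.fixture
def default_cfg():
    return ScoreConfig()


def random_structural_tree(rng: random.Random, n_leaves: int):
    """A random ordered binary tree with structural-style labels.

    Leaf positions are arbitrary (hairpin replacement scores 0, so only the
    shape and operator labels matter to the alignment).
    """
    if n_leaves == 1:
        i = rng.randrange(1, 50)
        return HairpinLeaf(i, i + rng.randrange(2, 10))
    split = rng.randrange(1, n_leaves)
    left = random_structural_tree(rng, split)
    right = random_structural_tree(rng, n_leaves - split)
    op = rng.choice([CONCAT_SYM, NEST_SYM, CROSS_SYM])
    if op == CROSS_SYM:
        return OperatorNode(op, left, right, h=rng.randrange(1, 4))
    return OperatorNode(op, left, right)
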