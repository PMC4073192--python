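import random
import warnings

import pytest

from mlsupertree import (InputTreeSet, SyntheticSpec, generate_inputs,
                         parse_newick, random_binary_tree)


@pytest.fixture
def quartet_ab_cd():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def quartet_ac_bd():
    return parse_newick("((A,C),(B,D));")


@pytest.fixture
def conflict_free_instance():
    """A 7-taxon truth with 30 perfect (distortion-free) subsamples."""
    truth = random_binary_tree("ABCDEFG", random.Random(42))
    inputs, record = generate_inputs(
        SyntheticSpec(truth, n_trees=30, subset_size_range=(4, 7),
                      distortion_rate=0.0, seed=42))
    return truth, inputs, record


@pytest.fixture(autouse=True)
def _silence_small_tree_warnings():
    """Small-overlap warnings are expected throughout; keep test output clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def random_polytomous_tree(taxa, rng):
    """A random tree that may contain polytomies (for round-trip tests)."""
    tree = random_binary_tree(taxa, rng)
    from mlsupertree.trees import Node, Tree

    def collapse(node):
        kids = []
        for c in node.children:
            collapse(c)
            # contract ~30% of internal edges into polytomies
            if not c.is_leaf and rng.random() < 0.3:
                kids.extend(c.children)
            else:
                kids.append(c)
        node.children = kids

    out = tree.copy()
    collapse(out.root)
    return Tree(out.root, out.rooted)
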