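import numpy as np
import pytest

from cpforest.cohort import default_cohort_spec, generate_cohort
from cpforest.forest import ExtractedTree, ForestStructure, TreeNode


@pytest.fixture(scope="session")
def cohort_2000():
    """Default study conditions at n=2000 (fixed seed), no missingness."""
    return generate_cohort(default_cohort_spec(n=2000, seed=7))


@pytest.fixture(scope="session")
def cohort_small():
    """A quick cohort for pipeline mechanics tests."""
    return generate_cohort(default_cohort_spec(n=400, seed=11))


def leaf(nid, value, samples=1):
    return TreeNode(nid, None, None, None, None, float(value), int(samples))


def split(nid, var, thr, left, right):
    return TreeNode(nid, var, float(thr), left, right, None, None)


@pytest.fixture
def make_tree():
    """Build an ExtractedTree from (node spec) tuples; see helpers leaf/split."""

    def _make(nodes):
        return ExtractedTree(nodes=tuple(nodes))

    return _make


@pytest.fixture
def depth1_forest():
    """One stump: root splits X at 3.0; left leaf value 1.2, right leaf 2.0."""
    tree = ExtractedTree(
        nodes=(split(0, "X", 3.0, 1, 2), leaf(1, 1.2, 5), leaf(2, 2.0, 3))
    )
    return ForestStructure(trees=(tree,), feature_names=("X", "Y"))


def random_extracted_forest(rng, n_trees=5, depth=3, variables=("A", "B", "C")):
    """Random well-formed ExtractedTree ensemble for property tests."""

    def grow(next_id, d):
        nodes = []

        def rec(d, force_split=False):
            nid = len(nodes)
            if d == 0 or (not force_split and rng.random() < 0.3):
                nodes.append(leaf(nid, float(rng.uniform(1, 5)), int(rng.integers(1, 30))))
                return nid
            nodes.append(None)  # placeholder
            var = str(rng.choice(variables))
            thr = float(rng.uniform(1, 5))
            left = rec(d - 1)
            right = rec(d - 1)
            nodes[nid] = split(nid, var, thr, left, right)
            return nid

        rec(d, force_split=True)  # root always splits
        return ExtractedTree(nodes=tuple(nodes))

    trees = tuple(grow(0, depth) for _ in range(n_trees))
    return ForestStructure(trees=trees, feature_names=tuple(variables))
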