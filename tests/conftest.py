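import numpy as np
import pytest

from phylogem.core_io import CharacterMatrix, parse_matrix, parse_newick


@pytest.fixture
def quartet_matrix():
    return parse_matrix("a\t00\nb\t00\nc\t11\nd\t11\n")


@pytest.fixture
def quartet_tree():
    return parse_newick("((a,b),(c,d));")


@pytest.fixture
def quartet_tree_alt():
    return parse_newick("((a,c),(b,d));")


def random_tree_and_matrix(rng: np.random.Generator, n_leaves: int,
                           n_char: int, n_states: int,
                           missing_prob: float = 0.0):
    """Random binary rooted tree + random matrix (independent of the
    package's own simulators)."""
    labels = [f"x{i}" for i in range(n_leaves)]
    # random sequential joining
    from phylogem.core_io import Node, PhyloTree
    nodes = [Node(lbl) for lbl in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree = PhyloTree(nodes[0])
    while True:
        rows = rng.integers(n_states, size=(n_leaves, n_char))
        cells = [[str(int(s)) for s in row] for row in rows]
        if missing_prob > 0:
            for i in range(n_leaves):
                for j in range(n_char):
                    if rng.random() < missing_prob:
                        cells[i][j] = "?" if rng.random() < 0.5 else "-"
        try:
            matrix = CharacterMatrix(labels, cells)
        except ValueError:
            continue    # a fully-missing character; redraw
        return tree, matrix
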