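"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic programs: parsimony length is
found by enumerating every internal-node state assignment, and range
reconstructions by enumerating every internal range assignment.
"""

from itertools import product

import numpy as np

from phylogem.core_io import CharacterMatrix, PhyloTree


def brute_force_fitch(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Minimum total changes over all internal state assignments.

    Ambiguous leaves (? / -) contribute no cost for any parent state.
    """
    internals = [n for n in tree.postorder() if not n.is_leaf()]
    idx = {id(n): i for i, n in enumerate(internals)}
    # edges between internals, and leaf edges
    int_edges = [(idx[id(n.parent)], idx[id(n)])
                 for n in internals if n.parent is not None]
    total = 0
    for j in range(matrix.n_char):
        states = matrix.observed_states(j)
        grid = np.array(list(product(states, repeat=len(internals))),
                        dtype=np.int64)           # (n_assign, n_internal)
        cost = np.zeros(len(grid), dtype=np.int64)
        for pi, ci in int_edges:
            cost += grid[:, pi] != grid[:, ci]
        for leaf in tree.leaves():
            tok = matrix.cell(leaf.label, j)
            if tok in "0123456789":
                cost += grid[:, idx[id(leaf.parent)]] != int(tok)
            # ambiguous leaf: free for any parent state
        total += int(cost.min())
    return total


def brute_force_single_trait(tree: PhyloTree, leaf_states: dict[str, int],
                             n_states: int) -> int:
    """Unordered single-character length by exhaustive enumeration."""
    internals = [n for n in tree.postorder() if not n.is_leaf()]
    best = None
    for assign in product(range(n_states), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        cost = 0
        for node in tree.postorder():
            if node.parent is None:
                continue
            s = (leaf_states[node.label] if node.is_leaf()
                 else amap[id(node)])
            cost += s != amap[id(node.parent)]
        if best is None or cost < best:
            best = cost
    return best
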