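"""Equal-weights unordered parsimony: tree length, fit indices, character
optimization (ACCTRAN/DELTRAN) and synapomorphy classification.

Scoring uses a unit-cost dynamic program over per-character state sets,
which is exact on binary trees and on polytomies alike.  Unknown ("?") and
inapplicable ("-") cells are both scored as full ambiguity (any observed
state); they differ only in reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .core_io import (CharacterMatrix, Node, PhyloTree, ValidationError,
                      check_leaf_join, _DIGITS)

_N_STATES = 10          # tokens are single digits 0-9
_INF = np.int64(1) << 20


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

@dataclass
class ParsimonyScores:
    total_length: int
    per_char_length: np.ndarray          # (n_char,) steps
    per_char_min: np.ndarray             # (n_char,) distinct observed states - 1
    per_char_max: np.ndarray             # (n_char,) star-tree steps
    ensemble_ci: float
    ensemble_ri: float
    downpass: dict[Node, np.ndarray] = field(default_factory=dict, repr=False)
    allowed: np.ndarray = field(default=None, repr=False)   # (10, n_char) bool

    @property
    def ci_2dp(self) -> float:
        return round(self.ensemble_ci, 2)

    @property
    def ri_2dp(self) -> float:
        return round(self.ensemble_ri, 2)


def _allowed_states(matrix: CharacterMatrix, taxa: list[str]) -> np.ndarray:
    """Boolean (10, n_char): state s observed for character j among *taxa*."""
    allowed = np.zeros((_N_STATES, matrix.n_char), dtype=bool)
    for t in taxa:
        for j, tok in enumerate(matrix.row(t)):
            if tok in _DIGITS:
                allowed[int(tok), j] = True
    return allowed


def _leaf_costs(matrix: CharacterMatrix, taxon: str,
                allowed: np.ndarray) -> np.ndarray:
    cost = np.full(allowed.shape, _INF, dtype=np.int64)
    for j, tok in enumerate(matrix.row(taxon)):
        if tok in _DIGITS:
            cost[int(tok), j] = 0
        else:                       # ? and - : any observed state
            cost[allowed[:, j], j] = 0
    return cost


def _downpass(tree: PhyloTree, matrix: CharacterMatrix,
              allowed: np.ndarray) -> dict[Node, np.ndarray]:
    """Unit-cost subtree cost vectors: cost[s, j] = min steps in the subtree
    given the node holds state s for character j."""
    cost: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            cost[node] = _leaf_costs(matrix, node.label, allowed)
        else:
            acc = np.zeros(allowed.shape, dtype=np.int64)
            for child in node.children:
                c = cost[child]
                acc += np.minimum(c, c.min(axis=0) + 1)
            np.minimum(acc, _INF, out=acc)
            acc[~allowed] = _INF
            cost[node] = acc
    return cost


def char_min_max(matrix: CharacterMatrix, j: int,
                 taxa: Optional[Iterable[str]] = None) -> tuple[int, int]:
    """Minimum conceivable steps and star-tree (maximum) steps of character
    *j*, counting only *taxa* (default: all) with observed states."""
    taxa = list(taxa) if taxa is not None else list(matrix.taxa)
    counts: dict[int, int] = {}
    for t in taxa:
        tok = matrix.cell(t, j)
        if tok in _DIGITS:
            counts[int(tok)] = counts.get(int(tok), 0) + 1
    if not counts:
        raise ValidationError(f"character {j} unobserved on the given taxa")
    n_obs = sum(counts.values())
    return len(counts) - 1, n_obs - max(counts.values())


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix) -> ParsimonyScores:
    """Parsimony length and ensemble fit indices of *matrix* on *tree*.

    Characters that are constant or unobserved on the tree's taxa score 0.
    ``ensemble_ci`` = sum(min)/sum(length) (1.0 when the total length is 0);
    ``ensemble_ri`` excludes characters with max == min from both terms.
    """
    leaves = tree.leaf_labels()
    check_leaf_join(tree, matrix.taxa, "matrix")
    allowed = _allowed_states(matrix, leaves)
    if not allowed.any(axis=0).all():
        bad = int(np.flatnonzero(~allowed.any(axis=0))[0])
        raise ValidationError(
            f"character {bad} has no observed state among tree taxa")
    down = _downpass(tree, matrix, allowed)
    per_len = down[tree.root].min(axis=0).astype(np.int64)
    mins = np.empty(matrix.n_char, dtype=np.int64)
    maxs = np.empty(matrix.n_char, dtype=np.int64)
    for j in range(matrix.n_char):
        mins[j], maxs[j] = char_min_max(matrix, j, leaves)
    total = int(per_len.sum())
    ci = float(mins.sum() / total) if total > 0 else 1.0
    informative = maxs > mins
    denom = int((maxs - mins)[informative].sum())
    ri = float((maxs - per_len)[informative].sum() / denom) if denom > 0 else 1.0
    return ParsimonyScores(total_length=total, per_char_length=per_len,
                           per_char_min=mins, per_char_max=maxs,
                           ensemble_ci=ci, ensemble_ri=ri,
                           downpass=down, allowed=allowed)


def edge_min_changes(tree: PhyloTree, matrix: CharacterMatrix,
                     scores: Optional[ParsimonyScores] = None) -> dict[Node, int]:
    """Minimum number of changes forced onto each branch over all
    most-parsimonious reconstructions.

    Keyed by the child node of each branch.  A branch maps to 0 when some
    MPR places no change on it for any character ("no unambiguous support").
    """
    if scores is None or not scores.downpass:
        scores = fitch_length(tree, matrix)
    down = scores.downpass
    length = scores.per_char_length

    def soft(c: np.ndarray) -> np.ndarray:
        return np.minimum(c, c.min(axis=0) + 1)

    outside: dict[Node, np.ndarray] = {}       # cost of tree minus subtree(v),
    result: dict[Node, int] = {}               # as a function of parent state
    for node in tree.preorder():
        if node is tree.root:
            b = np.zeros_like(down[node])
        else:
            a = outside[node]
            b = soft(a)
        # a 2-child root's two edges are the same unrooted branch: the
        # sibling may not shunt its change onto "its" root edge, so its
        # contribution enters raw (no +1 slack)
        root2 = node is tree.root and len(node.children) == 2
        for child in node.children:
            sib = sum((down[w] if root2 else soft(down[w])
                       for w in node.children if w is not child),
                      start=np.zeros_like(b))
            outside[child] = b + sib
        if node is not tree.root:
            no_change = (outside[node] + down[node]).min(axis=0)
            result[node] = int((no_change > length).sum())
    return result


# ---------------------------------------------------------------------------
# Character optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Change:
    character: int
    node: Node            # child end of the branch carrying the change
    from_state: int
    to_state: int


@dataclass
class StateReconstruction:
    flavor: str                                   # "ACCTRAN" | "DELTRAN"
    node_states: dict[Node, np.ndarray]           # (n_char,) int8 per node
    changes: list[Change]

    def changes_per_char(self, n_char: int) -> np.ndarray:
        out = np.zeros(n_char, dtype=np.int64)
        for ch in self.changes:
            out[ch.character] += 1
        return out

    def changes_on(self, node: Node) -> list[Change]:
        return [c for c in self.changes if c.node is node]


def optimize_states(tree: PhyloTree, matrix: CharacterMatrix, flavor: str = "DELTRAN",
                    scores: Optional[ParsimonyScores] = None) -> StateReconstruction:
    """Single most-parsimonious state assignment for every node and character.

    ACCTRAN resolves cost ties toward changing on the branch entering a node
    (changes pulled rootward); DELTRAN resolves them toward retaining the
    parent state (changes pushed tipward).  Either way the implied change
    count per character equals that character's parsimony length.
    """
    flavor = flavor.upper()
    if flavor not in ("ACCTRAN", "DELTRAN"):
        raise ValueError(f"unknown optimization flavor: {flavor!r}")
    if scores is None or not scores.downpass:
        scores = fitch_length(tree, matrix)
    down = scores.downpass
    n_char = matrix.n_char
    states: dict[Node, np.ndarray] = {}
    changes: list[Change] = []
    cols = np.arange(n_char)
    for node in tree.preorder():
        cost = down[node]
        if node is tree.root:
            states[node] = np.argmin(cost, axis=0).astype(np.int8)
            continue
        parent_states = states[node.parent]
        total = cost + 1
        total[parent_states, cols] -= 1          # staying put is free
        best = total.min(axis=0)
        is_min = total == best
        if flavor == "DELTRAN":
            keep = is_min[parent_states, cols]   # parent state attainable?
            assigned = np.where(keep, parent_states,
                                np.argmax(is_min, axis=0)).astype(np.int8)
        else:                                    # ACCTRAN: prefer changing here
            moved = is_min.copy()
            moved[parent_states, cols] = False   # mask out "no change"
            any_moved = moved.any(axis=0)
            assigned = np.where(any_moved, np.argmax(moved, axis=0),
                                parent_states).astype(np.int8)
        states[node] = assigned
        for j in np.flatnonzero(assigned != parent_states):
            changes.append(Change(int(j), node,
                                  int(parent_states[j]), int(assigned[j])))
    return StateReconstruction(flavor=flavor, node_states=states, changes=changes)


# ---------------------------------------------------------------------------
# Synapomorphies
# ---------------------------------------------------------------------------

def classify_synapomorphies(tree: PhyloTree, matrix: CharacterMatrix,
                            reconstruction: StateReconstruction,
                            clade: Iterable[str],
                            scores: Optional[ParsimonyScores] = None) -> dict:
    """Split the changes on a clade's stem branch into exclusive vs
    homoplastic.

    A stem change is *exclusive* when its character attains its minimum
    conceivable number of steps on the whole tree (character ci = 1);
    otherwise it is homoplastic.
    """
    node = tree.find_clade(clade)
    if node is None:
        raise ValidationError("clade is not a node of the tree")
    if scores is None:
        scores = fitch_length(tree, matrix)
    stem_changes = reconstruction.changes_on(node)
    exclusive, homoplastic = [], []
    for ch in stem_changes:
        if scores.per_char_length[ch.character] == scores.per_char_min[ch.character]:
            exclusive.append(ch)
        else:
            homoplastic.append(ch)
    return {"exclusive": exclusive, "homoplastic": homoplastic}


def changes_to_tsv(tree: PhyloTree, matrix: CharacterMatrix,
                   reconstruction: StateReconstruction) -> str:
    """Change list as TSV: character, branch (child-node label), from, to,
    flavor, exclusive flag."""
    scores = fitch_length(tree, matrix)
    labels: dict[Node, str] = {}
    counter = 0
    for node in tree.preorder():
        if node.label:
            labels[node] = node.label
        else:
            labels[node] = f"node{counter}"
            counter += 1
    lines = ["character\tbranch\tfrom\tto\tflavor\texclusive"]
    for ch in reconstruction.changes:
        excl = scores.per_char_length[ch.character] == scores.per_char_min[ch.character]
        lines.append("\t".join([str(ch.character), labels[ch.node],
                                str(ch.from_state), str(ch.to_state),
                                reconstruction.flavor,
                                "yes" if excl else "no"]))
    return "\n".join(lines) + "\n"
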