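"""Parsimony ancestral-state reconstruction of categorical traits (habitat,
body-size class, metanotal bristle extent) on a fixed topology.

Implemented as a self-contained single-character dynamic program (plain
Python sets/dicts), independent of the vectorized matrix scorer, so the two
can cross-check each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from .core_io import Node, PhyloTree, TraitTable, ValidationError

_SIZE_BASE_MM = 12.0
_SIZE_BIN_MM = 3.0
_SIZE_CLASSES = 6


@dataclass(frozen=True)
class SizeClassifier:
    """Six contiguous 3 mm body-length bins, lower bound inclusive."""
    base_mm: float = _SIZE_BASE_MM
    bin_mm: float = _SIZE_BIN_MM
    n_classes: int = _SIZE_CLASSES

    def boundaries(self) -> list[float]:
        return [self.base_mm + i * self.bin_mm for i in range(self.n_classes - 1)]

    def classify(self, length_mm: float) -> int:
        if length_mm <= 0:
            raise ValidationError(f"non-positive body length: {length_mm}")
        if length_mm < self.base_mm:
            return 0
        k = 1 + int((length_mm - self.base_mm) // self.bin_mm)
        return min(k, self.n_classes - 1)

    def label(self, cls: int) -> str:
        if cls == 0:
            return f"<{self.base_mm:g}mm"
        lo = self.base_mm + (cls - 1) * self.bin_mm
        if cls == self.n_classes - 1:
            return f">={lo:g}mm"
        return f"{lo:g}-{lo + self.bin_mm:g}mm"


def classify_size(length_mm: float) -> int:
    """Size class 0-5 of a body length in mm (0: <12, 1: [12,15), ... 5: >=24)."""
    return SizeClassifier().classify(length_mm)


@dataclass
class TraitChange:
    node: Node                 # child end of the branch carrying the change
    from_state: int
    to_state: int


@dataclass
class TraitReconstruction:
    trait: str
    state_labels: list[str]
    node_state_sets: dict[Node, frozenset[int]] = field(repr=False, default_factory=dict)
    total_steps: int = 0
    changes: list[TraitChange] = field(default_factory=list)

    @property
    def root_states(self) -> frozenset[int]:
        # the root is the first node touched by preorder insertion below
        return next(iter(self.node_state_sets.values()))

    def root_state_labels(self) -> list[str]:
        return [self.state_labels[s] for s in sorted(self.root_states)]


def reconstruct_trait(tree: PhyloTree, trait: TraitTable,
                      ordered: bool = False) -> TraitReconstruction:
    """Most-parsimonious ancestral states of a categorical trait.

    Every leaf must carry a state; ``node_state_sets`` holds the full set of
    states each node takes in at least one most-parsimonious reconstruction,
    so a singleton root set identifies the inferred ancestral state.  The
    reported change list is one minimal reconstruction (ties resolved by
    retaining the parental state).  ``ordered=True`` switches to Wagner
    (linear-scale) costs; the default is unordered (Fitch) parsimony.
    """
    for leaf in tree.leaves():
        if leaf.label not in trait.assignments:
            raise ValidationError(
                f"species {leaf.label!r} has no state for trait {trait.name!r}")

    states = list(range(len(trait.states)))

    def step(a: int, b: int) -> int:
        return abs(a - b) if ordered else int(a != b)

    inf = math.inf
    down: dict[Node, list[float]] = {}
    for node in tree.postorder():
        if node.is_leaf():
            s = trait.assignments[node.label]
            down[node] = [0.0 if t == s else inf for t in states]
        else:
            vec = [0.0] * len(states)
            for child in node.children:
                c = down[child]
                for s in states:
                    vec[s] += min(c[t] + step(s, t) for t in states)
            down[node] = vec

    total = min(down[tree.root])

    # outside costs (tree minus the node's subtree, by parent state)
    outside: dict[Node, list[float]] = {}
    sets: dict[Node, frozenset[int]] = {}
    for node in tree.preorder():
        if node is tree.root:
            through = [0.0] * len(states)
        else:
            a = outside[node]
            through = [min(a[p] + step(p, s) for p in states) for s in states]
        for child in node.children:
            sib = [0.0] * len(states)
            for other in node.children:
                if other is child:
                    continue
                c = down[other]
                for s in states:
                    sib[s] += min(c[t] + step(s, t) for t in states)
            outside[child] = [through[s] + sib[s] for s in states]
        here = down[node]
        sets[node] = frozenset(
            s for s in states if here[s] + through[s] == total)

    # one minimal assignment, delaying changes (DELTRAN-style tie-break)
    assigned: dict[Node, int] = {}
    changes: list[TraitChange] = []
    for node in tree.preorder():
        if node is tree.root:
            assigned[node] = min(s for s in states if down[node][s] == total)
            continue
        p = assigned[node.parent]
        costs = [down[node][s] + step(p, s) for s in states]
        best = min(costs)
        if costs[p] == best:
            choice = p
        else:
            choice = costs.index(best)
        assigned[node] = choice
        if choice != p:
            changes.append(TraitChange(node, p, choice))

    rec = TraitReconstruction(trait=trait.name, state_labels=list(trait.states))
    rec.node_state_sets = {n: sets[n] for n in tree.preorder()}
    rec.total_steps = int(total)
    rec.changes = changes
    return rec


def annotate_tree(tree: PhyloTree, rec: TraitReconstruction) -> None:
    """Attach the MPR state set of each node as a tree annotation."""
    key = rec.trait or "trait"
    for node, stateset in rec.node_state_sets.items():
        labels = "|".join(rec.state_labels[s] for s in sorted(stateset))
        node.annotations[key] = labels


def reconstruction_to_tsv(tree: PhyloTree, rec: TraitReconstruction) -> str:
    """Per-node state table: node label, MPR state set, change on stem."""
    lines = [f"node\t{rec.trait}_states\tchange_on_stem"]
    counter = 0
    names: dict[Node, str] = {}
    for node in tree.preorder():
        if node.label:
            names[node] = node.label
        else:
            names[node] = f"node{counter}"
            counter += 1
    stem_change = {c.node: c for c in rec.changes}
    for node in tree.preorder():
        stateset = "|".join(rec.state_labels[s]
                            for s in sorted(rec.node_state_sets[node]))
        ch = stem_change.get(node)
        desc = (f"{rec.state_labels[ch.from_state]}->{rec.state_labels[ch.to_state]}"
                if ch else "")
        lines.append(f"{names[node]}\t{stateset}\t{desc}")
    return "\n".join(lines) + "\n"
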