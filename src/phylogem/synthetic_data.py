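"""Ground-truth generators: matrices evolved on known trees, range histories
built from scripted ideal events, and traits with planted changes.

Every generator is a pure function of its arguments and seed.  Branch
"lengths" are abstract change counts; there is no clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import (CharacterMatrix, Node, PhyloTree, TraitTable,
                      ValidationError)
from .gem_biogeography import (EVENTS, GemConfig, GemReconstruction, NodeEvent,
                               Pixel, PixelRange, event_cost,
                               _internal_postorder)


@dataclass(frozen=True)
class SimulationRecipe:
    n_taxa: int = 8
    n_char: int = 20
    n_states: int = 2
    change_rate: float = 0.2      # expected changes per branch per character
    tree_shape: str = "yule"      # yule | pectinate
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValidationError("need at least 4 taxa")
        if not 2 <= self.n_states <= 10:
            raise ValidationError("n_states must be in 2..10")
        if self.change_rate < 0:
            raise ValidationError("change_rate must be >= 0")


def _leaf_name(i: int, width: int) -> str:
    return f"t{i:0{width}d}"


def simulate_tree(n_taxa: int, shape: str = "yule",
                  seed: int = 0) -> PhyloTree:
    """Random binary rooted tree with leaves t01..tNN."""
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    labels = [_leaf_name(i + 1, width) for i in range(n_taxa)]
    if shape == "pectinate":
        node = Node(labels[-1])
        for lbl in reversed(labels[:-1]):
            parent = Node()
            parent.add_child(Node(lbl))
            parent.add_child(node)
            node = parent
        return PhyloTree(node)
    if shape != "yule":
        raise ValidationError(f"unknown tree shape: {shape!r}")
    root = Node()
    root.add_child(Node(labels[0]))
    root.add_child(Node(labels[1]))
    tips = list(root.children)
    for lbl in labels[2:]:
        tip = tips.pop(int(rng.integers(len(tips))))
        left = Node(tip.label)
        right = Node(lbl)
        tip.label = None
        tip.add_child(left)
        tip.add_child(right)
        tips.extend([left, right])
    return PhyloTree(root)


def simulate_matrix(recipe: SimulationRecipe
                    ) -> tuple[PhyloTree, CharacterMatrix, int]:
    """Evolve characters by Poisson change counts per branch; each change
    picks a uniformly random *different* state.  Returns the true tree, the
    leaf matrix and the total number of realized changes."""
    rng = np.random.default_rng(recipe.seed)
    tree = simulate_tree(recipe.n_taxa, recipe.tree_shape, recipe.seed + 1)
    leaves = tree.leaf_labels()
    states: dict[Node, np.ndarray] = {}
    total_changes = 0
    for node in tree.preorder():
        if node is tree.root:
            states[node] = rng.integers(recipe.n_states, size=recipe.n_char)
            continue
        cur = states[node.parent].copy()
        n_events = rng.poisson(recipe.change_rate, size=recipe.n_char)
        for j in np.flatnonzero(n_events):
            for _ in range(int(n_events[j])):
                shift = int(rng.integers(1, recipe.n_states))
                cur[j] = (cur[j] + shift) % recipe.n_states
                total_changes += 1
        states[node] = cur
    rows = [[str(int(s)) for s in states[leaf]] for leaf in tree.leaves()]
    matrix = CharacterMatrix(leaves, rows)
    return tree, matrix, total_changes


# ---------------------------------------------------------------------------
# Range histories
# ---------------------------------------------------------------------------

def simulate_range_history(tree: PhyloTree, event_script: Sequence[str],
                           root_range: PixelRange, z: int = 10, seed: int = 0,
                           noise: float = 0.0,
                           config: Optional[GemConfig] = None
                           ) -> tuple[dict[str, PixelRange], GemReconstruction]:
    """Propagate ranges root-to-tips applying one scripted ideal event per
    internal node (script order = preorder over internal nodes).

    vicariance: random partition (error on 1-pixel ranges); sympatry: both
    children copy; founder: second child gets one fresh pixel outside the
    ancestor; point_sympatry: second child gets one pixel inside it.
    Optional noise adds/drops one tip pixel with the given probability.
    Returns terminal ranges and the scripted reconstruction at its cost.
    """
    rng = np.random.default_rng(seed)
    if config is None:
        config = GemConfig(z=z, seed=seed)
    internal = [n for n in tree.preorder() if not n.is_leaf()]
    if len(event_script) != len(internal):
        raise ValidationError(
            f"script has {len(event_script)} events for {len(internal)} "
            f"internal nodes")
    for ev in event_script:
        if ev not in EVENTS:
            raise ValidationError(f"unknown event type: {ev!r}")
    if not root_range or len(root_range) > z:
        raise ValidationError("root range must be non-empty and within Z")
    events = dict(zip(internal, event_script))
    ranges: dict[Node, PixelRange] = {tree.root: frozenset(root_range)}
    fresh_counter = 0
    used = set(root_range)

    def fresh_pixel() -> Pixel:
        nonlocal fresh_counter
        while True:
            p = (10_000 + fresh_counter, 0)
            fresh_counter += 1
            if p not in used:
                used.add(p)
                return p

    for node in tree.preorder():
        if node.is_leaf():
            continue
        if len(node.children) != 2:
            raise ValidationError("range history requires a binary tree")
        A = ranges[node]
        ev = events[node]
        c1, c2 = node.children
        if ev == "vicariance":
            pixels = sorted(A)
            if len(pixels) < 2:
                raise ValidationError(
                    "vicariance requested on a 1-pixel range (unsplittable)")
            cut = int(rng.integers(1, len(pixels)))
            perm = rng.permutation(len(pixels))
            side1 = frozenset(pixels[i] for i in perm[:cut])
            ranges[c1], ranges[c2] = side1, frozenset(A - side1)
        elif ev == "sympatry":
            ranges[c1] = ranges[c2] = A
        elif ev == "founder":
            ranges[c1] = A
            ranges[c2] = frozenset({fresh_pixel()})
        else:   # point_sympatry
            ranges[c1] = A
            pixels = sorted(A)
            ranges[c2] = frozenset({pixels[int(rng.integers(len(pixels)))]})

    terminal: dict[str, PixelRange] = {}
    for leaf in tree.leaves():
        r = set(ranges[leaf])
        if noise > 0:
            if rng.random() < noise:
                r.add(fresh_pixel())
            if len(r) > 1 and rng.random() < noise:
                r.discard(sorted(r)[int(rng.integers(len(r)))])
        terminal[leaf.label] = frozenset(r)

    truth = GemReconstruction()
    census = {e: 0 for e in EVENTS}
    total = 0.0
    for node in _internal_postorder(tree):
        A = ranges[node]
        d1, d2 = ranges[node.children[0]], ranges[node.children[1]]
        ev = events[node]
        cost = event_cost(ev, A, d1, d2, config)
        truth.node_events[node] = NodeEvent(ev, cost)
        truth.node_ranges[node] = A
        census[ev] += 1
        total += cost
    truth.total_cost = total
    truth.census = census
    return terminal, truth


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_trait(tree: PhyloTree, n_states: int, n_changes: int,
                   seed: int = 0, name: str = "trait"
                   ) -> tuple[TraitTable, list[tuple[Node, int, int]]]:
    """Plant exactly *n_changes* state changes on distinct branches and read
    the leaf states off the tips."""
    if n_states < 1:
        raise ValidationError("n_states must be >= 1")
    branches = [n for n in tree.preorder() if n is not tree.root]
    if n_changes > len(branches):
        raise ValidationError(
            f"cannot place {n_changes} changes on {len(branches)} branches")
    if n_changes > 0 and n_states < 2:
        raise ValidationError("changes require at least 2 states")
    rng = np.random.default_rng(seed)
    chosen = {branches[int(i)]
              for i in rng.choice(len(branches), size=n_changes, replace=False)}
    states: dict[Node, int] = {tree.root: 0}
    placements: list[tuple[Node, int, int]] = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        s = states[node.parent]
        if node in chosen:
            shift = int(rng.integers(1, n_states))
            new = (s + shift) % n_states
            placements.append((node, s, new))
            s = new
        states[node] = s
    labels = [f"s{i}" for i in range(n_states)]
    assignments = {leaf.label: states[leaf] for leaf in tree.leaves()}
    return TraitTable(name=name, states=labels, assignments=assignments), placements
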