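"""Heuristic most-parsimonious-tree search, strict consensus and Bremer
support.

Searches are over unrooted topologies (represented internally as rooted
binary trees; length is rooting-invariant) and results are rooted on a
declared outgroup taxon.  Tree identity is the set of non-trivial
bipartitions, optionally after collapsing branches with no unambiguous
support under any most-parsimonious reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .core_io import (CharacterMatrix, Node, PhyloTree, ValidationError,
                      normalize_name)
from .parsimony_core import edge_min_changes, fitch_length

_PENALTY = 10 ** 9      # effective-length penalty for constraint violations


@dataclass
class SearchConfig:
    n_replicates: int = 10
    hold_per_replicate: int = 10
    swapper: str = "TBR"             # TBR | SPR | NNI
    seed: int = 0
    slack: int = 0                   # keep trees within best+slack steps
    collapse: str = "no-unambiguous-support"   # none | min-length-zero | ...

    def __post_init__(self):
        if self.n_replicates < 1 or self.hold_per_replicate < 1:
            raise ValueError("n_replicates and hold_per_replicate must be >= 1")
        if self.slack < 0:
            raise ValueError("slack must be >= 0")
        if self.swapper not in ("TBR", "SPR", "NNI"):
            raise ValueError(f"unknown swapper: {self.swapper!r}")


@dataclass
class TreeSet:
    """Distinct topologies (bipartition identity) with their lengths."""
    trees: list[PhyloTree] = field(default_factory=list)
    lengths: list[int] = field(default_factory=list)

    @property
    def best_length(self) -> int:
        return min(self.lengths)

    def best_trees(self) -> list[PhyloTree]:
        best = self.best_length
        return [t for t, l in zip(self.trees, self.lengths) if l == best]

    def __len__(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# Tree surgery helpers
# ---------------------------------------------------------------------------

def _copy_with_map(tree: PhyloTree) -> tuple[PhyloTree, dict[Node, Node]]:
    mapping: dict[Node, Node] = {}

    def rec(node: Node) -> Node:
        clone = Node(node.label)
        mapping[node] = clone
        for c in node.children:
            clone.add_child(rec(c))
        return clone

    return PhyloTree(rec(tree.root)), mapping


def _detach(tree: PhyloTree, node: Node) -> tuple[PhyloTree, PhyloTree]:
    """Copy of (tree minus subtree(node), subtree(node)); unifurcations suppressed."""
    t, m = _copy_with_map(tree)
    v = m[node]
    parent = v.parent
    parent.remove_child(v)
    sub = PhyloTree(v)
    if parent is t.root:
        main = PhyloTree(parent.children[0])
        main.root.parent = None
    else:
        grand = parent.parent
        sibling = parent.children[0]
        i = grand.children.index(parent)
        grand.children[i] = sibling
        sibling.parent = grand
        main = PhyloTree(t.root)
    return main, sub


def _regraft(main: PhyloTree, sub: PhyloTree,
             edge_child: Optional[Node]) -> PhyloTree:
    """Attach *sub* onto the branch above *edge_child* of *main* (None: above
    the root).  Inputs are consumed (no further use by the caller)."""
    if edge_child is None:
        new_root = Node()
        new_root.add_child(main.root)
        new_root.add_child(sub.root)
        return PhyloTree(new_root)
    parent = edge_child.parent
    joint = Node()
    i = parent.children.index(edge_child)
    parent.children[i] = joint
    joint.parent = parent
    joint.add_child(edge_child)
    joint.add_child(sub.root)
    return PhyloTree(main.root)


def reroot_above(tree: PhyloTree, node: Node) -> PhyloTree:
    """New tree rooted on the branch above *node* (a copy; input unchanged)."""
    if node.parent is None:
        return tree.copy()
    t, m = _copy_with_map(tree)
    target = m[node]
    new_root = Node()
    p = target.parent
    p.remove_child(target)
    new_root.add_child(target)
    prev, cur = new_root, p
    while cur is not None:
        nxt = cur.parent
        if nxt is not None:
            nxt.children.remove(cur)
        cur.parent = None
        prev.add_child(cur)
        prev, cur = cur, nxt
    out = PhyloTree(new_root)
    out.suppress_unifurcations()
    return out


def root_with_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root so the outgroup leaf is one of the root's two children."""
    outgroup = normalize_name(outgroup)
    leaf = next((n for n in tree.postorder()
                 if n.is_leaf() and n.label == outgroup), None)
    if leaf is None:
        raise ValidationError(f"outgroup {outgroup!r} not a leaf of the tree")
    return reroot_above(tree, leaf)


def _rerootings(sub: PhyloTree) -> list[PhyloTree]:
    if sub.n_leaves() <= 2:
        return [sub]
    out = [sub]
    skip_one_root_child = True
    for node in sub.preorder():
        if node is sub.root:
            continue
        if node.parent is sub.root:
            if skip_one_root_child:     # both root edges = same unrooted edge
                skip_one_root_child = False
                continue
        out.append(reroot_above(sub, node))
    return out


def _edge_children(tree: PhyloTree) -> list[Optional[Node]]:
    """Attachment positions: every non-root node plus None (above the root)."""
    return [n for n in tree.preorder() if n is not tree.root] + [None]


def _neighbors(tree: PhyloTree, swapper: str) -> Iterator[PhyloTree]:
    if swapper == "NNI":
        yield from _nni_neighbors(tree)
        return
    prune_sites = [n for n in tree.preorder() if n is not tree.root]
    for site in prune_sites:
        main, sub = _detach(tree, site)
        if main.n_leaves() < 1:
            continue
        variants = [sub] if swapper == "SPR" else _rerootings(sub)
        for variant in variants:
            for pos in _edge_children(main):
                main_copy, m = _copy_with_map(main)
                sub_copy, _ = _copy_with_map(variant)
                yield _regraft(main_copy, sub_copy,
                               None if pos is None else m[pos])


def _nni_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    for node in tree.preorder():
        if node.is_leaf() or node.parent is None:
            continue
        parent = node.parent
        siblings = [c for c in parent.children if c is not node]
        for sib in siblings:
            for child in node.children:
                t, m = _copy_with_map(tree)
                a, b = m[sib], m[child]
                pa, pb = a.parent, b.parent
                ia, ib = pa.children.index(a), pb.children.index(b)
                pa.children[ia], pb.children[ib] = b, a
                a.parent, b.parent = pb, pa
                yield t


# ---------------------------------------------------------------------------
# Topology identity / collapsing
# ---------------------------------------------------------------------------

def collapsed_bipartitions(tree: PhyloTree, matrix: CharacterMatrix,
                           rule: str) -> frozenset[frozenset[str]]:
    """Bipartition identity of a tree under a branch-collapsing rule.

    ``min-length-zero`` and ``no-unambiguous-support`` both drop branches
    whose forced change count over all MPRs is zero (for independent,
    unordered characters the two formulations coincide)."""
    if rule == "none":
        return tree.bipartitions()
    if rule not in ("min-length-zero", "no-unambiguous-support"):
        raise ValueError(f"unknown collapse rule: {rule!r}")
    emin = edge_min_changes(tree, matrix)
    all_leaves = frozenset(tree.leaf_labels())
    ref = min(all_leaves)
    sets: dict[int, frozenset[str]] = {}
    out = set()
    for node in tree.postorder():
        if node.is_leaf():
            sets[id(node)] = frozenset([node.label])
            continue
        s = frozenset().union(*(sets[id(c)] for c in node.children))
        sets[id(node)] = s
        if node is tree.root or emin.get(node, 1) == 0:
            continue
        side = all_leaves - s if ref in s else s
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return frozenset(out)


def collapse_tree(tree: PhyloTree, matrix: CharacterMatrix,
                  rule: str) -> PhyloTree:
    """Copy of *tree* with unsupported internal branches contracted."""
    if rule == "none":
        return tree.copy()
    emin = edge_min_changes(tree, matrix)
    t, m = _copy_with_map(tree)
    for node in list(tree.postorder()):
        if node.is_leaf() or node is tree.root:
            continue
        if emin.get(node, 1) == 0:
            clone = m[node]
            parent = clone.parent
            i = parent.children.index(clone)
            parent.children[i:i + 1] = clone.children
            for c in clone.children:
                c.parent = parent
    return t


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

def _contains_clade(tree: PhyloTree, clade: frozenset[str]) -> bool:
    all_leaves = frozenset(tree.leaf_labels())
    ref = min(all_leaves)
    side = all_leaves - clade if ref in clade else clade
    if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
        return True                  # trivial split: present in every tree
    return side in tree.bipartitions()


def _effective_length(tree: PhyloTree, matrix: CharacterMatrix,
                      constraint: Optional[frozenset[str]],
                      converse: bool) -> tuple[int, int]:
    length = fitch_length(tree, matrix).total_length
    if constraint is not None:
        has = _contains_clade(tree, constraint)
        if (converse and has) or (not converse and not has):
            return length + _PENALTY, length
    return length, length


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def _random_addition(matrix: CharacterMatrix, order: list[str],
                     constraint, converse) -> PhyloTree:
    root = Node()
    inner = Node()
    inner.add_child(Node(order[0]))
    inner.add_child(Node(order[1]))
    root.add_child(inner)
    root.add_child(Node(order[2]))
    tree = PhyloTree(root)
    for label in order[3:]:
        best_tree, best_len = None, None
        positions = _edge_children(tree)[:-1]   # no insertion above the root
        skip = tree.root.children[1]            # duplicate unrooted root edge
        for pos in positions:
            if pos is skip:
                continue
            main, m = _copy_with_map(tree)
            cand = _regraft(main, PhyloTree(Node(label)), m[pos])
            eff, _ = _effective_length(cand, matrix, constraint, converse)
            if best_len is None or eff < best_len:
                best_tree, best_len = cand, eff
        tree = best_tree
    return tree


def heuristic_search(matrix: CharacterMatrix, config: SearchConfig,
                     outgroup: str,
                     constraint: Optional[Iterable[str]] = None,
                     converse: bool = False) -> TreeSet:
    """Random-addition + branch-swapping search for minimum-length trees.

    Returns all distinct topologies (under ``config.collapse`` identity) at
    the best length found, plus any within ``config.slack`` extra steps.
    Deterministic for a given seed; replicate *i* draws from a stream seeded
    by ``(seed, i)`` so enlarging ``n_replicates`` only adds replicates.
    When ``converse`` is true only trees *not* containing the constraint
    clade are retained.
    """
    if matrix.n_taxa < 4:
        raise ValidationError("search requires at least 4 taxa")
    outgroup = normalize_name(outgroup)
    if outgroup not in matrix.taxa:
        raise ValidationError(f"outgroup {outgroup!r} not in matrix")
    clade = None
    if constraint is not None:
        clade = frozenset(normalize_name(x) for x in constraint)
        extra = clade - set(matrix.taxa)
        if extra:
            raise ValidationError(f"constraint taxa not in matrix: {sorted(extra)}")

    archive: dict[frozenset, tuple[PhyloTree, int]] = {}
    best_eff: Optional[int] = None

    def consider(tree: PhyloTree) -> tuple[int, bool]:
        nonlocal best_eff
        eff, length = _effective_length(tree, matrix, clade, converse)
        if best_eff is None or eff < best_eff:
            best_eff = eff
            for k in [k for k, (_, e) in archive.items()
                      if e > best_eff + config.slack]:
                del archive[k]
        if eff <= best_eff + config.slack and eff < _PENALTY:
            key = collapsed_bipartitions(tree, matrix, config.collapse)
            if key not in archive:
                archive[key] = (tree, eff)
                return eff, True
        return eff, False

    for rep in range(config.n_replicates):
        rng = np.random.default_rng((config.seed, rep))
        order = [matrix.taxa[i] for i in rng.permutation(matrix.n_taxa)]
        current = _random_addition(matrix, order, clade, converse)
        cur_eff, _ = _effective_length(current, matrix, clade, converse)
        consider(current)
        # first-improvement hill climb to a local optimum, holding
        # equal-length distinct neighbors for further swapping
        queue = [current]
        explored = 0
        held = 1
        while queue:
            tree = queue.pop(0)
            explored += 1
            restart = True
            while restart:
                restart = False
                for nb in _neighbors(tree, config.swapper):
                    eff, _ = _effective_length(nb, matrix, clade, converse)
                    if eff < cur_eff:
                        cur_eff = eff
                        tree = nb
                        queue.clear()
                        held = 1
                        consider(nb)
                        restart = True
                        break
                    if eff == cur_eff and held < config.hold_per_replicate:
                        _, fresh = consider(nb)
                        if fresh:
                            queue.append(nb)
                            held += 1
            if explored >= config.hold_per_replicate:
                break

    if not archive:
        raise ValidationError("no tree satisfied the constraint")
    result = TreeSet()
    for key, (tree, eff) in sorted(archive.items(),
                                   key=lambda kv: (kv[1][1], sorted(map(sorted, kv[0])))):
        result.trees.append(root_with_outgroup(tree, outgroup))
        result.lengths.append(eff)
    return result


def exhaustive_search(matrix: CharacterMatrix, outgroup: str,
                      constraint: Optional[Iterable[str]] = None,
                      converse: bool = False,
                      collapse: str = "none") -> TreeSet:
    """Enumerate every unrooted topology (feasible for <= ~9 taxa)."""
    outgroup = normalize_name(outgroup)
    clade = (frozenset(normalize_name(x) for x in constraint)
             if constraint is not None else None)
    taxa = matrix.taxa
    if len(taxa) < 3:
        raise ValidationError("need at least 3 taxa")
    best: Optional[int] = None
    archive: dict[frozenset, tuple[PhyloTree, int]] = {}

    def expand(tree: PhyloTree, remaining: list[str]):
        nonlocal best
        if not remaining:
            eff, _ = _effective_length(tree, matrix, clade, converse)
            if eff >= _PENALTY:
                return
            if best is None or eff < best:
                best = eff
                for k in [k for k, (_, e) in archive.items() if e > best]:
                    del archive[k]
            if eff == best:
                key = collapsed_bipartitions(tree, matrix, collapse)
                archive.setdefault(key, (tree, eff))
            return
        label, rest = remaining[0], remaining[1:]
        skip = tree.root.children[1]
        for pos in _edge_children(tree)[:-1]:
            if pos is skip:
                continue
            main, m = _copy_with_map(tree)
            expand(_regraft(main, PhyloTree(Node(label)), m[pos]), rest)

    root = Node()
    inner = Node()
    inner.add_child(Node(taxa[0]))
    inner.add_child(Node(taxa[1]))
    root.add_child(inner)
    root.add_child(Node(taxa[2]))
    expand(PhyloTree(root), list(taxa[3:]))
    if not archive:
        raise ValidationError("no tree satisfied the constraint")
    result = TreeSet()
    for key, (tree, eff) in sorted(archive.items(),
                                   key=lambda kv: sorted(map(sorted, kv[0]))):
        result.trees.append(root_with_outgroup(tree, outgroup))
        result.lengths.append(eff)
    return result


# ---------------------------------------------------------------------------
# Consensus and support
# ---------------------------------------------------------------------------

def strict_consensus(trees: Iterable[PhyloTree]) -> PhyloTree:
    """Rooted strict consensus: exactly the clades present in every tree."""
    trees = list(trees)
    if not trees:
        raise ValidationError("no trees to summarize")
    leafset = frozenset(trees[0].leaf_labels())
    for t in trees[1:]:
        if frozenset(t.leaf_labels()) != leafset:
            raise ValidationError("trees have mismatched leaf sets")
    common = trees[0].clades()
    for t in trees[1:]:
        common &= t.clades()
    clades = sorted(common, key=len, reverse=True)
    root = Node()
    node_of: list[tuple[frozenset, Node]] = [(leafset, root)]
    for clade in clades:
        parent = next(n for s, n in node_of if clade <= s)
        node = Node()
        parent.add_child(node)
        node_of.insert(0, (clade, node))
    for leaf in sorted(leafset):
        parent = next(n for s, n in node_of if leaf in s)
        parent.add_child(Node(leaf))
    return PhyloTree(root)


def bremer_support(matrix: CharacterMatrix, best: TreeSet,
                   clade: Iterable[str], config: SearchConfig,
                   outgroup: str) -> int:
    """Decay index via a converse-constraint search: extra steps needed for
    the shortest tree in which *clade* is not monophyletic."""
    clade = frozenset(normalize_name(x) for x in clade)
    all_taxa = frozenset(best.best_trees()[0].leaf_labels())
    if len(clade) <= 1 or len(clade) >= len(all_taxa) - 1:
        raise ValidationError(
            "clade is a trivial unrooted bipartition; its Bremer support "
            "is undefined (every tree contains it)")
    if not all(_contains_clade(t, clade) for t in best.best_trees()):
        raise ValidationError("clade absent from the strict consensus")
    converse = heuristic_search(matrix, config, outgroup,
                                constraint=clade, converse=True)
    return converse.best_length - best.best_length
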