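"""Geographically-explicit event model of range evolution on a pixel grid.

Occurrences are rasterized to integer-degree grid cells; every internal node
of a rooted binary tree receives an ancestral pixel range and one of four
events (vicariance, sympatry, founder, point sympatry).  The total
reconstruction cost — per-event cost plus pixel gains/losses along branches,
embodied in the per-event formulas — is minimized by a seeded flipping
(single-pixel toggle) local search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .core_io import Node, OccurrenceTable, PhyloTree, ValidationError

Pixel = tuple[int, int]
PixelRange = frozenset  # of Pixel

EVENTS = ("vicariance", "sympatry", "founder", "point_sympatry")


@dataclass(frozen=True)
class RasterGrid:
    pixel_size: float = 1.0
    fill: int = 1

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValidationError("pixel size must be positive")
        if self.fill < 1:
            raise ValidationError("fill must be >= 1")

    def pixel_of(self, lon: float, lat: float) -> Pixel:
        return (math.floor(lon / self.pixel_size),
                math.floor(lat / self.pixel_size))

    def footprint(self, lon: float, lat: float) -> frozenset:
        """Pixels occupied by one record: a fill x fill block anchored at the
        containing cell (fill=1: just that cell)."""
        px, py = self.pixel_of(lon, lat)
        r = self.fill // 2
        offsets = range(-r, self.fill - r)
        return frozenset((px + dx, py + dy) for dx in offsets for dy in offsets)


@dataclass(frozen=True)
class GemConfig:
    c_vic: float = 1.0
    c_sym: float = 1.0
    c_pnt: float = 1.0
    c_fnd: float = 1.0
    z: int = 10                  # max ancestral range size, in pixels
    runs: int = 10
    replicates: int = 10_000
    seed: int = 0
    soft_z: bool = False         # penalize (+1/pixel) instead of forbidding >Z
    slack: float = 0.0           # also report reconstructions within best+slack

    def __post_init__(self):
        if min(self.c_vic, self.c_sym, self.c_pnt, self.c_fnd) < 0:
            raise ValidationError("event costs must be >= 0")
        if self.z < 1:
            raise ValidationError("Z must be >= 1")


def rasterize(records: OccurrenceTable, grid: RasterGrid = RasterGrid(),
              taxa: Optional[Iterable[str]] = None) -> dict[str, PixelRange]:
    """Per-taxon occupied pixel sets.  With *taxa* given, every listed taxon
    must have at least one record."""
    ranges: dict[str, set] = {}
    for rec in records.records:
        ranges.setdefault(rec.taxon, set()).update(grid.footprint(rec.lon, rec.lat))
    if taxa is not None:
        missing = [t for t in taxa if t not in ranges]
        if missing:
            raise ValidationError(f"taxa with no occurrence record: {missing}")
    return {t: frozenset(p) for t, p in ranges.items()}


# ---------------------------------------------------------------------------
# Event costs
# ---------------------------------------------------------------------------

def _vicariance(A, D1, D2, cfg) -> float:
    return len(D1 & D2) + len(A ^ (D1 | D2)) + cfg.c_vic


def _sympatry(A, D1, D2, cfg) -> float:
    return len(A ^ D1) + len(A ^ D2) + cfg.c_sym


def _point_sympatry(A, D1, D2, cfg) -> float:
    """D2 is the point lineage; pixels outside the ancestral range are an
    extra cost.  A disjoint point lineage is implausible: overlap term 1."""
    ov = len(D1 & D2)
    return ((ov - 1 if ov >= 1 else 1)
            + len((D1 | D2) - A) + len(A - D1) + cfg.c_pnt)


def _founder(A, D1, D2, cfg) -> float:
    """D2 is the founder; overlap of the founder with the ancestral range is
    an extra cost (the founder establishes outside it)."""
    return (len(D2) - 1) + len(D2 & A) + len(A ^ D1) + cfg.c_fnd


def event_cost(event: str, A: PixelRange, D1: PixelRange, D2: PixelRange,
               config: GemConfig = GemConfig()) -> float:
    """Cost of assigning *event* at a node with ancestral range A and
    descendant ranges D1, D2.  Asymmetric events (founder, point sympatry)
    are evaluated in both orientations and the cheaper is returned."""
    if not D1 or not D2:
        raise ValidationError("descendant range is empty")
    if event == "vicariance":
        return _vicariance(A, D1, D2, config)
    if event == "sympatry":
        return _sympatry(A, D1, D2, config)
    if event == "point_sympatry":
        return min(_point_sympatry(A, D1, D2, config),
                   _point_sympatry(A, D2, D1, config))
    if event == "founder":
        return min(_founder(A, D1, D2, config),
                   _founder(A, D2, D1, config))
    raise ValidationError(f"unknown event type: {event!r}")


@dataclass(frozen=True)
class NodeEvent:
    event: str
    cost: float
    founder_child: Optional[int] = None   # 0/1: which child is the new lineage


def node_assignment(A: PixelRange, D1: PixelRange, D2: PixelRange,
                    config: GemConfig = GemConfig()) -> NodeEvent:
    """Cheapest event for a node; ties break in the fixed order
    vicariance > sympatry > founder > point sympatry."""
    if not D1 or not D2:
        raise ValidationError("descendant range is empty")
    candidates = [NodeEvent("vicariance", _vicariance(A, D1, D2, config)),
                  NodeEvent("sympatry", _sympatry(A, D1, D2, config))]
    f01 = _founder(A, D1, D2, config)      # D2 is the founder
    f10 = _founder(A, D2, D1, config)
    candidates.append(NodeEvent("founder", min(f01, f10),
                                founder_child=1 if f01 <= f10 else 0))
    p01 = _point_sympatry(A, D1, D2, config)
    p10 = _point_sympatry(A, D2, D1, config)
    candidates.append(NodeEvent("point_sympatry", min(p01, p10),
                                founder_child=1 if p01 <= p10 else 0))
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.cost < best.cost:
            best = cand
    return best


# ---------------------------------------------------------------------------
# Whole-tree reconstruction
# ---------------------------------------------------------------------------

@dataclass
class GemReconstruction:
    node_ranges: dict[Node, PixelRange] = field(default_factory=dict, repr=False)
    node_events: dict[Node, NodeEvent] = field(default_factory=dict, repr=False)
    total_cost: float = 0.0
    census: dict[str, int] = field(default_factory=dict)

    def key(self, internal_order: list[Node]) -> tuple:
        return tuple((self.node_events[n].event,
                      tuple(sorted(self.node_ranges[n])))
                     for n in internal_order)


def _internal_postorder(tree: PhyloTree) -> list[Node]:
    return [n for n in tree.postorder() if not n.is_leaf()]


def _range_of(node: Node, terminal_ranges, internal_ranges) -> PixelRange:
    if node.is_leaf():
        try:
            return terminal_ranges[node.label]
        except KeyError:
            raise ValidationError(f"leaf {node.label!r} has no range") from None
    return internal_ranges[node]


def reconstruction_cost(tree: PhyloTree, terminal_ranges: dict[str, PixelRange],
                        internal_ranges: dict[Node, PixelRange],
                        config: GemConfig = GemConfig()) -> GemReconstruction:
    """Score a complete assignment of ancestral ranges: per node the cheapest
    event is chosen, and costs (plus any soft-Z penalty) are summed."""
    rec = GemReconstruction()
    census = {e: 0 for e in EVENTS}
    total = 0.0
    for node in _internal_postorder(tree):
        if len(node.children) != 2:
            raise ValidationError("GEM requires a binary rooted tree")
        A = internal_ranges[node]
        if not A:
            raise ValidationError("empty ancestral range")
        if len(A) > config.z:
            if not config.soft_z:
                raise ValidationError(
                    f"ancestral range of size {len(A)} exceeds Z={config.z}")
            total += len(A) - config.z
        d1, d2 = (_range_of(c, terminal_ranges, internal_ranges)
                  for c in node.children)
        ev = node_assignment(A, d1, d2, config)
        rec.node_events[node] = ev
        rec.node_ranges[node] = A
        census[ev.event] += 1
        total += ev.cost
    rec.total_cost = total
    rec.census = census
    return rec


# ---------------------------------------------------------------------------
# Flipping search
# ---------------------------------------------------------------------------

def _init_ranges(tree: PhyloTree, terminal_ranges, config: GemConfig,
                 rng: np.random.Generator,
                 universe: list[Pixel]) -> dict[Node, PixelRange]:
    """Random initialization: per node one of (a) child intersection, else
    union truncated to Z, (b) random subset of the child union, (c) copy of
    one child."""
    ranges: dict[Node, PixelRange] = {}

    def trunc(pixels: set) -> frozenset:
        pixels = sorted(pixels)
        if len(pixels) <= config.z:
            return frozenset(pixels)
        idx = rng.choice(len(pixels), size=config.z, replace=False)
        return frozenset(pixels[i] for i in idx)

    for node in _internal_postorder(tree):
        kids = [_range_of(c, terminal_ranges, ranges) for c in node.children]
        union = set().union(*kids)
        mode = rng.integers(3)
        if mode == 0:
            inter = frozenset.intersection(*[frozenset(k) for k in kids])
            chosen = inter if inter else union
        elif mode == 1:
            size = int(rng.integers(1, min(config.z, len(union)) + 1))
            pixels = sorted(union)
            idx = rng.choice(len(pixels), size=min(size, len(pixels)),
                             replace=False)
            chosen = {pixels[i] for i in idx}
        else:
            chosen = set(kids[int(rng.integers(len(kids)))])
        ranges[node] = trunc(set(chosen))
    return ranges


def _node_cost(node: Node, ranges, terminal_ranges, config) -> float:
    A = ranges[node]
    d1, d2 = (_range_of(c, terminal_ranges, ranges) for c in node.children)
    cost = node_assignment(A, d1, d2, config).cost
    if config.soft_z and len(A) > config.z:
        cost += len(A) - config.z
    return cost


def _climb(tree: PhyloTree, terminal_ranges, ranges, config,
           rng: np.random.Generator, universe: list[Pixel]) -> float:
    """Single-pixel flipping to a strict local optimum; returns final cost."""
    internal = _internal_postorder(tree)
    costs = {n: _node_cost(n, ranges, terminal_ranges, config) for n in internal}
    total = sum(costs.values())
    improved = True
    while improved:
        improved = False
        for ni in rng.permutation(len(internal)):
            node = internal[int(ni)]
            for pi in rng.permutation(len(universe)):
                pixel = universe[int(pi)]
                current = ranges[node]
                if pixel in current:
                    if len(current) == 1:
                        continue
                    proposal = current - {pixel}
                else:
                    if len(current) >= config.z and not config.soft_z:
                        continue
                    proposal = current | {pixel}
                affected = [node]
                if node.parent is not None:
                    affected.append(node.parent)
                old = {n: costs[n] for n in affected}
                ranges[node] = proposal
                new = {n: _node_cost(n, ranges, terminal_ranges, config)
                       for n in affected}
                delta = sum(new.values()) - sum(old.values())
                if delta < 0:
                    costs.update(new)
                    total += delta
                    improved = True
                else:
                    ranges[node] = current
    return total


def flip_search(tree: PhyloTree, terminal_ranges: dict[str, PixelRange],
                config: GemConfig = GemConfig()) -> list[GemReconstruction]:
    """Replicated flipping search; returns all distinct reconstructions at
    the best cost found (plus any within ``config.slack``), best first."""
    for leaf in tree.leaves():
        if leaf.label not in terminal_ranges or not terminal_ranges[leaf.label]:
            raise ValidationError(f"leaf {leaf.label!r} has no pixel range")
    internal = _internal_postorder(tree)
    universe = sorted(set().union(*terminal_ranges.values()))
    best_cost = math.inf
    found: dict[tuple, GemReconstruction] = {}
    for run in range(config.runs):
        for rep in range(config.replicates):
            rng = np.random.default_rng((config.seed, run, rep))
            ranges = _init_ranges(tree, terminal_ranges, config, rng, universe)
            cost = _climb(tree, terminal_ranges, ranges, config, rng, universe)
            if cost > best_cost + config.slack:
                continue
            rec = reconstruction_cost(tree, terminal_ranges, ranges, config)
            if rec.total_cost < best_cost:
                best_cost = rec.total_cost
                for k in [k for k, r in found.items()
                          if r.total_cost > best_cost + config.slack]:
                    del found[k]
            found.setdefault(rec.key(internal), rec)
    return sorted(found.values(), key=lambda r: (r.total_cost, r.key(internal)))


def exhaustive_range_search(tree: PhyloTree,
                            terminal_ranges: dict[str, PixelRange],
                            config: GemConfig = GemConfig()) -> GemReconstruction:
    """Exact minimization over all internal range assignments (tiny instances
    only: cost grows as (2^pixels)^internal_nodes)."""
    from itertools import combinations

    internal = _internal_postorder(tree)
    universe = sorted(set().union(*terminal_ranges.values()))
    candidates = []
    max_size = min(config.z, len(universe))
    for size in range(1, max_size + 1):
        candidates.extend(frozenset(c) for c in combinations(universe, size))
    best: Optional[GemReconstruction] = None

    def assign(i: int, ranges: dict[Node, PixelRange]):
        nonlocal best
        if i == len(internal):
            rec = reconstruction_cost(tree, terminal_ranges, ranges, config)
            if best is None or rec.total_cost < best.total_cost:
                best = rec
            return
        for cand in candidates:
            ranges[internal[i]] = cand
            assign(i + 1, ranges)

    assign(0, {})
    return best


def permutation_test(tree: PhyloTree, terminal_ranges: dict[str, PixelRange],
                     config: GemConfig = GemConfig(), n_perm: int = 10,
                     perm_config: Optional[GemConfig] = None
                     ) -> tuple[float, list[float]]:
    """Observed best cost vs costs after permuting the taxon->range map.

    Permutations are re-searched at reduced effort (``perm_config``,
    defaulting to a single run with 1% of the replicates)."""
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = flip_search(tree, terminal_ranges, config)[0].total_cost
    if perm_config is None:
        perm_config = replace(config, runs=1,
                              replicates=max(1, config.replicates // 100))
    taxa = sorted(terminal_ranges)
    pools = [terminal_ranges[t] for t in taxa]
    permuted_costs = []
    for i in range(n_perm):
        rng = np.random.default_rng((config.seed, 7919, i))
        perm = rng.permutation(len(taxa))
        shuffled = {taxa[j]: pools[int(perm[j])] for j in range(len(taxa))}
        cfg = replace(perm_config, seed=perm_config.seed + 1000 + i)
        permuted_costs.append(flip_search(tree, shuffled, cfg)[0].total_cost)
    return observed, permuted_costs
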