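"""Shared data model and readers/writers for matrices, trees, records and traits.

All readers normalize taxon names (spaces become underscores) so that
matrices, trees, occurrence tables and trait tables join reliably.
Malformed input is rejected with an error naming the offending row or
character; there is no silent coercion.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

UNKNOWN = "?"
INAPPLICABLE = "-"
_DIGITS = frozenset("0123456789")
_VALID_TOKENS = _DIGITS | {UNKNOWN, INAPPLICABLE}


class FormatError(ValueError):
    """Malformed external input (bad token, ragged row, unparsable tree)."""


class ValidationError(ValueError):
    """Structurally parsable input violating a data-model invariant."""


def normalize_name(name: str) -> str:
    return name.strip().replace(" ", "_")


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------

class CharacterMatrix:
    """Taxa x characters state table.

    Cells hold single-character tokens: digits ``0``-``9``, ``?`` (unknown)
    or ``-`` (inapplicable).  Rows must all have the same length, taxon
    labels must be unique and non-empty, and every character must have at
    least one observed (digit) state.
    """

    def __init__(self, taxa: Sequence[str], rows: Sequence[Sequence[str]]):
        taxa = [normalize_name(t) for t in taxa]
        if len(taxa) != len(rows):
            raise ValidationError(
                f"{len(taxa)} taxa but {len(rows)} rows")
        if not taxa:
            raise ValidationError("empty matrix")
        seen = set()
        for t in taxa:
            if not t:
                raise ValidationError("empty taxon label")
            if t in seen:
                raise ValidationError(f"duplicate taxon label: {t!r}")
            seen.add(t)
        n_char = len(rows[0])
        cells = []
        for t, row in zip(taxa, rows):
            row = list(row)
            if len(row) != n_char:
                raise FormatError(
                    f"ragged row for taxon {t!r}: expected {n_char} tokens, "
                    f"got {len(row)}")
            for j, tok in enumerate(row):
                if tok not in _VALID_TOKENS:
                    raise FormatError(
                        f"unknown state symbol {tok!r} at taxon {t!r}, "
                        f"character {j}")
            cells.append(row)
        for j in range(n_char):
            if all(cells[i][j] not in _DIGITS for i in range(len(taxa))):
                raise ValidationError(
                    f"character {j} has no observed state (all missing)")
        self.taxa: list[str] = taxa
        self._cells: list[list[str]] = cells
        self._index = {t: i for i, t in enumerate(taxa)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self._cells[0])

    def cell(self, taxon: str, j: int) -> str:
        return self._cells[self._index[taxon]][j]

    def row(self, taxon: str) -> list[str]:
        return list(self._cells[self._index[taxon]])

    def observed_states(self, j: int, taxa: Optional[Iterable[str]] = None) -> list[int]:
        """Sorted distinct digit states of character *j* among *taxa* (default all)."""
        idx = range(self.n_taxa) if taxa is None else (self._index[t] for t in taxa)
        return sorted({int(self._cells[i][j]) for i in idx
                       if self._cells[i][j] in _DIGITS})

    def subset(self, taxa: Sequence[str]) -> "CharacterMatrix":
        missing = [t for t in taxa if normalize_name(t) not in self._index]
        if missing:
            raise ValidationError(f"taxa not in matrix: {missing}")
        return CharacterMatrix(list(taxa), [self.row(normalize_name(t)) for t in taxa])

    def __eq__(self, other) -> bool:
        return (isinstance(other, CharacterMatrix)
                and self.taxa == other.taxa and self._cells == other._cells)

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_char} characters>"


def read_matrix(path: str | os.PathLike, dialect: str = "tsv") -> CharacterMatrix:
    """Read a character matrix in ``tsv``, ``tnt`` (xread subset) or ``nexus``."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    return parse_matrix(text, dialect)


def parse_matrix(text: str, dialect: str = "tsv") -> CharacterMatrix:
    if dialect == "tsv":
        return _parse_matrix_tsv(text)
    if dialect == "tnt":
        return _parse_matrix_tnt(text)
    if dialect == "nexus":
        return _parse_matrix_nexus(text)
    raise FormatError(f"unknown matrix dialect: {dialect!r}")


def _parse_matrix_tsv(text: str) -> CharacterMatrix:
    taxa, rows = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"line {lineno}: expected taxon<TAB>states")
        taxa.append(parts[0])
        rows.append(list("".join(p.strip() for p in parts[1:])))
    if not taxa:
        raise FormatError("empty matrix file")
    return CharacterMatrix(taxa, rows)


def _parse_matrix_tnt(text: str) -> CharacterMatrix:
    # Minimal xread subset:  xread ['title'] nchar ntax  <rows>  ;
    tokens = text.replace(";", " ; ").split()
    if not tokens or tokens[0].lower() != "xread":
        raise FormatError("TNT matrix must start with 'xread'")
    pos = 1
    if pos < len(tokens) and tokens[pos].startswith("'"):
        while pos < len(tokens) and not tokens[pos].endswith("'"):
            pos += 1
        pos += 1
    try:
        n_char, n_taxa = int(tokens[pos]), int(tokens[pos + 1])
    except (IndexError, ValueError) as exc:
        raise FormatError("xread header must give nchar ntax") from exc
    pos += 2
    taxa, rows = [], []
    for _ in range(n_taxa):
        if pos + 1 >= len(tokens) or tokens[pos] == ";":
            raise FormatError("xread: fewer rows than declared ntax")
        taxa.append(tokens[pos])
        rows.append(list(tokens[pos + 1]))
        pos += 2
    m = CharacterMatrix(taxa, rows)
    if m.n_char != n_char:
        raise FormatError(
            f"xread declares {n_char} characters but rows have {m.n_char}")
    return m


def _parse_matrix_nexus(text: str) -> CharacterMatrix:
    try:
        dmat = dendropy.StandardCharacterMatrix.get(
            data=text, schema="nexus")
    except Exception as exc:  # dendropy raises assorted error types
        raise FormatError(f"NEXUS parse failure: {exc}") from exc
    taxa, rows = [], []
    for taxon in dmat.taxon_namespace:
        seq = dmat[taxon]
        taxa.append(taxon.label)
        rows.append([str(c) for c in seq.symbols_as_list()])
    return CharacterMatrix(taxa, rows)


def write_matrix(matrix: CharacterMatrix, path: str | os.PathLike,
                 dialect: str = "tsv") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_matrix(matrix, dialect))


def format_matrix(matrix: CharacterMatrix, dialect: str = "tsv") -> str:
    if dialect == "tsv":
        return "".join(f"{t}\t{''.join(matrix.row(t))}\n" for t in matrix.taxa)
    if dialect == "tnt":
        out = [f"xread {matrix.n_char} {matrix.n_taxa}"]
        out += [f"{t} {''.join(matrix.row(t))}" for t in matrix.taxa]
        out.append(";")
        return "\n".join(out) + "\n"
    raise FormatError(f"unsupported output dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """Tree node with parent/child links and a free-form annotation map."""

    __slots__ = ("label", "parent", "children", "annotations")

    def __init__(self, label: Optional[str] = None):
        self.label = label
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.annotations: dict[str, object] = {}

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:
        return f"<Node {self.label!r}>" if self.label else "<Node>"


class PhyloTree:
    """Rooted tree with uniquely labeled leaves.

    Internal nodes may carry labels and annotations.  Polytomies are
    permitted (consensus trees); operations that require binary trees check
    explicitly.
    """

    def __init__(self, root: Node):
        self.root = root
        labels = [n.label for n in self.leaves()]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate leaf labels")
        if any(not lbl for lbl in labels):
            raise ValidationError("unlabeled leaf")

    # -- traversal ----------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    # -- structure ----------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            clone = Node(node.label)
            clone.annotations = dict(node.annotations)
            for c in node.children:
                clone.add_child(rec(c))
            return clone
        return PhyloTree(rec(self.root))

    def find_clade(self, leaf_set: Iterable[str]) -> Optional[Node]:
        """Node whose descendant leaf set equals *leaf_set*, or None."""
        target = frozenset(normalize_name(x) for x in leaf_set)
        for node, below in self._leafsets():
            if below == target:
                return node
        return None

    def _leafsets(self) -> list[tuple[Node, frozenset[str]]]:
        sets: dict[int, frozenset[str]] = {}
        out = []
        for node in self.postorder():
            if node.is_leaf():
                s = frozenset([node.label])
            else:
                s = frozenset().union(*(sets[id(c)] for c in node.children))
            sets[id(node)] = s
            out.append((node, s))
        return out

    def clades(self, trivial: bool = False) -> set[frozenset[str]]:
        """Leaf sets below internal nodes (rooted clades)."""
        all_leaves = frozenset(self.leaf_labels())
        out = set()
        for node, s in self._leafsets():
            if node.is_leaf() or node is self.root:
                continue
            if trivial or 1 < len(s) < len(all_leaves):
                out.add(s)
        return out

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial unrooted bipartitions, canonicalized to the side not
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        out = set()
        for node, s in self._leafsets():
            if node.is_leaf() or node is self.root:
                continue
            side = all_leaves - s if ref in s else s
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return frozenset(out)

    def suppress_unifurcations(self) -> None:
        for node in list(self.postorder()):
            while len(node.children) == 1 and node is not self.root:
                child = node.children[0]
                parent = node.parent
                i = parent.children.index(node)
                parent.children[i] = child
                child.parent = parent
                node = parent
        while len(self.root.children) == 1:
            self.root = self.root.children[0]
            self.root.parent = None

    def restrict(self, keep: Iterable[str]) -> "PhyloTree":
        """Subtree induced by the leaf labels in *keep*."""
        keep = {normalize_name(k) for k in keep}
        missing = keep - set(self.leaf_labels())
        if missing:
            raise ValidationError(f"leaves not in tree: {sorted(missing)}")

        def rec(node: Node) -> Optional[Node]:
            if node.is_leaf():
                if node.label in keep:
                    clone = Node(node.label)
                    clone.annotations = dict(node.annotations)
                    return clone
                return None
            kids = [k for k in (rec(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            clone = Node(node.label)
            clone.annotations = dict(node.annotations)
            for k in kids:
                clone.add_child(k)
            return clone

        new_root = rec(self.root)
        if new_root is None:
            raise ValidationError("restriction removed every leaf")
        return PhyloTree(new_root)

    def __repr__(self) -> str:
        return f"<PhyloTree {self.n_leaves()} leaves>"


def parse_newick(text: str) -> PhyloTree:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(
                    f"unbalanced ')' at character offset {offset}")
    if depth != 0:
        raise FormatError(
            f"unbalanced '(' (depth {depth} at end of input, "
            f"offset {len(text)})")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise FormatError(f"newick parse failure: {exc}") from exc

    def rec(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(normalize_name(label or ""))
        else:
            node = Node(normalize_name(dnode.label) if dnode.label else None)
            for dchild in dnode.child_nodes():
                node.add_child(rec(dchild))
        return node

    return PhyloTree(rec(dtree.seed_node))


def read_newick(path: str | os.PathLike) -> PhyloTree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree, path: Optional[str | os.PathLike] = None,
                 annotations: bool = False) -> str:
    text = format_newick(tree, annotations=annotations)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def format_newick(tree: PhyloTree, annotations: bool = False) -> str:
    def ann(node: Node) -> str:
        if not (annotations and node.annotations):
            return ""
        inner = ",".join(f"{k}={node.annotations[k]}"
                         for k in sorted(node.annotations))
        return f"[&{inner}]"

    def rec(node: Node) -> str:
        if node.is_leaf():
            return node.label + ann(node)
        inner = ",".join(rec(c) for c in node.children)
        return f"({inner}){node.label or ''}{ann(node)}"

    return rec(tree.root) + ";"


def read_gem_trees(path: str | os.PathLike) -> list[PhyloTree]:
    """GEM 'trees' tab dialect: one Newick per line, '#' comments skipped."""
    trees = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            trees.append(parse_newick(line))
    if not trees:
        raise FormatError("no trees found")
    return trees


# ---------------------------------------------------------------------------
# Occurrence records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccurrenceRecord:
    taxon: str
    lon: float
    lat: float


@dataclass
class OccurrenceTable:
    records: list[OccurrenceRecord] = field(default_factory=list)

    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.taxon)
        return list(seen)

    def for_taxon(self, taxon: str) -> list[OccurrenceRecord]:
        taxon = normalize_name(taxon)
        return [r for r in self.records if r.taxon == taxon]


def read_records(path: str | os.PathLike) -> OccurrenceTable:
    """GEM 'records' tab dialect: taxon, longitude, latitude; '#' comments."""
    table = OccurrenceTable()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"row {lineno}: expected 'taxon lon lat', got {len(parts)} fields")
            taxon = normalize_name(parts[0])
            if not taxon:
                raise ValidationError(f"row {lineno}: empty taxon field")
            try:
                lon, lat = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"row {lineno}: unparsable coordinate") from exc
            if not -180.0 <= lon <= 180.0:
                raise ValidationError(
                    f"row {lineno}: longitude {lon} out of [-180, 180]")
            if not -90.0 <= lat <= 90.0:
                raise ValidationError(
                    f"row {lineno}: latitude {lat} out of [-90, 90]")
            table.records.append(OccurrenceRecord(taxon, lon, lat))
    if not table.records:
        raise FormatError("no records found")
    return table


def write_records(table: OccurrenceTable, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# taxon lon lat\n")
        for r in table.records:
            fh.write(f"{r.taxon}\t{r.lon:.6g}\t{r.lat:.6g}\n")


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Species -> categorical state for one named trait.

    ``states`` is the ordered list of state labels; ``assignments`` maps
    species to a state index into that list.
    """

    name: str
    states: list[str]
    assignments: dict[str, int]
    definitions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for sp, idx in self.assignments.items():
            if not 0 <= idx < len(self.states):
                raise ValidationError(
                    f"state index {idx} for {sp!r} outside declared range")

    def state_of(self, species: str) -> str:
        return self.states[self.assignments[normalize_name(species)]]

    def species(self) -> list[str]:
        return list(self.assignments)


def read_trait_table(path: str | os.PathLike) -> TraitTable:
    """Trait TSV: '# trait: NAME' and '# states: A B C' headers, then
    species<TAB>state rows."""
    name: Optional[str] = None
    states: Optional[list[str]] = None
    assignments: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise FormatError("empty trait file")
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("trait:"):
                name = body[len("trait:"):].strip()
            elif body.lower().startswith("states:"):
                states = body[len("states:"):].split()
            continue
        if name is None or states is None:
            raise FormatError(
                f"row {lineno}: data before '# trait:'/'# states:' headers")
        parts = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(parts) != 2:
            raise FormatError(f"row {lineno}: expected species<TAB>state")
        species, state = normalize_name(parts[0]), parts[1].strip()
        if state not in states:
            raise ValidationError(
                f"row {lineno}: state {state!r} not in declared set {states}")
        if species in assignments:
            raise ValidationError(f"row {lineno}: duplicate species {species!r}")
        assignments[species] = states.index(state)
    if not assignments:
        raise FormatError("trait file has headers but no rows")
    return TraitTable(name=name, states=states, assignments=assignments)


def write_trait_table(table: TraitTable, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# trait: {table.name}\n")
        fh.write(f"# states: {' '.join(table.states)}\n")
        for sp in table.assignments:
            fh.write(f"{sp}\t{table.states[table.assignments[sp]]}\n")


def check_leaf_join(tree: PhyloTree, names: Iterable[str], what: str) -> None:
    """Raise if any tree leaf is missing from *names* (matrix/trait join)."""
    available = set(names)
    missing = [lbl for lbl in tree.leaf_labels() if lbl not in available]
    if missing:
        raise ValidationError(
            f"tree leaves missing from {what}: {sorted(missing)}")
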