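"""Bundled reference data: the 28-species *Eidmanacris* ingroup topology and
the published ecological trait classifications (habitat, 3 mm body-size
class, metanotal bristle extent).

The topology was transcribed from the published cladogram description; trait
states come from the printed species table.  All files are plain text under
``phylogem/data``.
"""

from __future__ import annotations

from importlib import resources

from .core_io import PhyloTree, TraitTable, parse_newick, read_trait_table

TRAIT_NAMES = ("habitat", "size_class", "metanotal_bristles")


def _data_text(filename: str) -> str:
    return (resources.files("phylogem") / "data" / filename).read_text(
        encoding="utf-8")


def eidmanacris_ingroup_tree() -> PhyloTree:
    """Rooted binary topology of the 28 ingroup species (named clades A-N2)."""
    return parse_newick(_data_text("eidmanacris_ingroup_tree.nwk"))


def eidmanacris_trait(name: str) -> TraitTable:
    """One of the bundled trait tables: habitat (str / str-cav / cav),
    size_class (six 3 mm bins, see :class:`SizeClassifier`) or
    metanotal_bristles (anterior / entire)."""
    if name not in TRAIT_NAMES:
        raise KeyError(f"unknown trait {name!r}; available: {TRAIT_NAMES}")
    with resources.as_file(resources.files("phylogem") / "data"
                           / f"{name}.tsv") as path:
        return read_trait_table(path)
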