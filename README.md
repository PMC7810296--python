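# phylogem

A tested, reusable pipeline for three analyses commonly combined in
morphology-based systematics of poorly-sampled taxa:

1. **Equal-weights unordered parsimony** — heuristic tree search (random
   addition + NNI/SPR/TBR branch swapping), strict consensus, ensemble
   consistency/retention indices, ACCTRAN/DELTRAN character optimization,
   synapomorphy classification and Bremer support via converse-constraint
   searches.
2. **Parsimony ancestral-state reconstruction** of categorical traits
   (habitat class, 3 mm body-size bins, metanotal bristle extent) on a fixed
   topology, with full most-parsimonious state sets per node.
3. **Geographically-explicit event-based biogeography** — occurrence records
   rasterized to a 1°×1° pixel grid; every internal node receives an
   ancestral pixel range and one of four events (vicariance, sympatry,
   founder, point sympatry); the total event-plus-range-change cost is
   minimized with a seeded flipping search, with permutation tests.

A synthetic-data module generates matrices evolved on known trees, range
histories built from scripted ideal events, and traits with planted changes,
so every stage is testable against known ground truth.

The package bundles a small reference dataset (`phylogem/data/`): the
28-species *Eidmanacris* cricket ingroup topology with named clades, and the
published habitat / size-class / bristle-extent classifications.

## Command line

```sh
# heuristic parsimony search
phylogem search --matrix matrix.tsv --outgroup Melanotes_ornata \
    --replicates 1000 --hold 100 --seed 1 --collapse no-unambiguous-support

# ancestral states of a categorical trait on a fixed tree
phylogem asr --tree tree.nwk --trait habitat.tsv

# event-based range reconstruction
phylogem gem --tree tree.nwk --records records.tab \
    --pixel 1.0 --fill 1 --z 10 --runs 10 --replicates 10000 --seed 1

# simulate a matrix with known ground truth
phylogem simulate --taxa 20 --chars 100 --rate 0.1 --seed 1 --out-prefix sim

# full multi-stage pipeline from a YAML config
phylogem run --config run.yml
```

`run.yml` keys: `matrix`, `matrix_dialect`, `outgroup`, `tree`, `records`,
`traits` (list), `clades` (name → leaf list), `search` (replicates, hold,
swapper, seed, collapse), `gem` (costs, z, runs, replicates, seed),
`pixel_size`, `fill`, `n_perm`, `out_dir`. The pipeline writes
`summary.json` / `summary.txt` plus Newick outputs; identical inputs and
seeds give byte-identical summaries.

## File formats

* Matrices: TSV (`taxon<TAB>0101?-...`), a minimal TNT `xread` subset, and
  the NEXUS CHARACTERS/MATRIX block. States are digits 0–9; `?` unknown,
  `-` inapplicable (both scored as full ambiguity).
* Trees: Newick (internal labels and `[&key=value]` annotations supported);
  "trees" tab files are one Newick per line, `#` comments skipped.
* Occurrence records: whitespace-separated `taxon lon lat` rows.
* Trait tables: TSV with `# trait:` and `# states:` headers.

Taxon names are normalized (spaces → underscores) at read time so matrices,
trees, records and trait tables join reliably.

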