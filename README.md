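# treederep

Taxonomy-aware dereplication of OTU-dense phylogenetic trees.

Large similarity-search-derived trees are often crowded with redundant
OTUs: orthologs from many closely related organisms, or recently
duplicated lineage-specific paralogs. `treederep` reduces that density
reproducibly. It scans a rooted Newick tree for highly supported
clades whose OTUs all belong to one user-defined taxonomic category,
merges nested hits into the most inclusive ("largest") such clades,
and within each collapses the membership down to a fixed number of
representatives — the leaves whose basal-node-to-leaf path lengths lie
closest to the clade median (the median damps the pull of unusually
long branches). Everything outside those clades, and every OTU the
taxonomy table does not cover, is left untouched, so taxonomic breadth
is preserved while redundancy goes away.

## Inputs

1. **Tree** — one Newick statement, rooted as written. Support values
   may be internal-node labels (`(A,B)0.97:0.1`, the default) or
   bracketed branch comments (`(A,B):0.1[0.97]`, select with
   `--support-style comment`). Supports are compared on whatever
   scale the file uses (0–1 or 0–100); pick the threshold to match.
   Branch lengths are optional; missing lengths count as 0 in depth
   sums.
2. **Taxonomy TSV** (optional) — `<otu_name>\t<rank1>;<rank2>;...`,
   `#` comments allowed. Ranks are positional (1 = most inclusive);
   labels can be anything: taxa, sample sites, project tags. Without
   this file no rule can match and nothing is removed.
3. **Parameter file** — line-oriented:

   ```
   threshold	0.8
   rule	Viridiplantae	2	2
   default	3	2
   ```

   `threshold 0` examines every internal node. Each `rule` names a
   category, the 1-based lineage rank at which to test it, and how
   many OTUs to retain per clade. The optional `default` applies to
   any clade unanimous at the given rank that no explicit rule covers.

Clades with fewer members than their retain count are skipped
entirely; clades with exactly that many are reported but lose nothing.

## CLI

```sh
treederep --tree tree.nwk --taxonomy lineages.tsv --params params.txt --out results/
```

writes three files into `results/`:

- `retained_otus.txt` — the retained-OTU list (one per line) plus a
  `#`-commented per-clade summary; this is the functional output.
- `reference_tree.nwk` — the input topology restricted to the retained
  leaves, as a cladogram (no branch lengths; for visual reference, not
  analysis).
- `removal_table.tsv` — machine-readable per-clade removal records.

Exit codes: 0 success, 2 usage error, 3 input validation error. Logs
go to stderr (`--quiet` / `--verbose` adjust). Runs are fully
deterministic: identical inputs give byte-identical outputs.

## Library

```python
from treederep import parse_newick, load_taxonomy, load_params, dereplicate

tree = parse_newick(open("tree.nwk").read())
taxonomy = load_taxonomy(open("lineages.tsv").read())
params = load_params(open("params.txt").read())
result = dereplicate(tree, taxonomy, params)
result.retained_otus   # tuple of kept leaf names, in tree order
result.records         # per-clade removal records
```

`treederep.synthetic` generates random trees with planted supported
clades plus matching taxonomy tables (`generate_tree`, `write_fixture`)
and hosts `brute_force_dereplicate`, an independent straight-line
reimplementation used to cross-check the main path in the tests.

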