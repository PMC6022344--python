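# famground

A library and CLI for working with a curated protein family/complex
ontology: reading, validating, and writing its five tabular resource files,
resolving multi-level `isa`/`partof` hierarchies down to gene members,
grounding entity strings from text with affix-aware normalization,
exporting/importing OBO, proposing cross-ontology equivalences by
member-set comparison, discovering synonym candidates by edit distance,
and computing grounding-evaluation statistics.

## Resource format

Five CSV files (UTF-8, no header row) in one directory:

| file | columns |
|---|---|
| `entities.csv` | identifier |
| `relations.csv` | subject_ns, subject_id, relation (`isa`\|`partof`), object_ns, object_id |
| `grounding_map.csv` | text, target_ns, target_id |
| `equivalences.csv` | external_ns, external_id, famplex_id |
| `gene_prefixes.csv` | pattern, position (`prefix`\|`suffix`), category, [species_tag] |

Affix patterns contain exactly one `{Gene name}` placeholder and are
matched case-sensitively. The resource's own namespace defaults to `FPLX`.

## Library overview

- `famground.ontology_io` — loaders/writers for the five files, structural
  validation (duplicates, dangling endpoints, cycles), OBO 1.2 export and a
  round-trip OBO parser.
- `famground.hierarchy` — ancestors/descendants, gene-member expansion,
  top/intermediate/placeholder classification, subsumed depth, child-count
  statistics, grounding-level classification.
- `famground.grounder` — iterative longest-match-first affix stripping with
  per-category semantics (polarity inversion for inhibition affixes,
  species tags, protein-state modifiers, mRNA flag), grounding-map lookup
  (exact by default, optional case-insensitive fallback), and expansion of
  grounded entities to gene members.
- `famground.xref_mapper` — member-set equivalence proposals (exact-set,
  subset, Jaccard modes) and Levenshtein-based synonym candidates.
- `famground.eval_stats` — per-category accuracy tables with binomial
  standard errors, cumulative-occurrence curves and top-percentile shares,
  event-coverage proportions, grounding-level distributions, and coverage
  arithmetic.
- `famground.fixtures` — a deterministic worked-example ontology (NFkappaB,
  ERK, AMPK, PLC, RAS, RAF, placeholder categories, example affixes) plus
  seeded random ontology and gold-labeled mention-corpus generators.

```python
from famground import fixtures, grounder, hierarchy

ontology = fixtures.build_inpaper_ontology()
graph = hierarchy.build_graph(ontology)

result, genes = grounder.ground_and_expand("shRNA-ERK 1/2", ontology, graph=graph)
result.entity            # FPLX:ERK
result.polarity_inverted  # True — inhibition affix flips event polarity
sorted(g.identifier for g in genes)  # ['MAPK1', 'MAPK3']
```

## CLI

```bash
famground validate <dir>                 # check the five resource files
famground export-obo <dir> -o out.obo    # OBO 1.2 export
famground expand NFkappaB                # gene-level members
famground stats <dir>                    # level classes, depths, child stats
famground ground "mmu-AKT1" "NF-kB"      # TSV grounding results
famground ground --tsv mentions.tsv
famground map-xrefs --famplex fam.tsv --external other.tsv --mode exact_set
famground eval --annotations samples.tsv # accuracy table with SEs
famground eval --freqs counts.tsv --curve curve.tsv
famground simulate --seed 7 --mentions 500 -o corpus.tsv
```

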