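# ctxabc

Context-gated ABC-model discovery over literature-derived entity-relation
tables.

The classic closed-discovery ABC model links a fixed entity pair (A, C)
through intermediate B entities that co-occur with both, which produces many
spurious paths. `ctxabc` implements two refinements: every entity relation
carries a four-slot *biological context* (cell, drug, disease, organism)
extracted from conditioning clauses of its sentence, and an A–B relation is
only connected to a B–C relation when their contexts agree. Agreement is
scored per slot as `1 − distance / max_distance` over a MeSH-style tree of
dotted positions and aggregated cosine-style as
`Σ slot similarities / sqrt(n1·n2)`, where `n_i` counts the identified slots
of each relation. A third variant first propagates the union of an
abstract's contexts to all relations of that abstract ("context
assignment"), trading some precision for recall.

## Layout

| Module | Purpose |
| --- | --- |
| `ctxabc.relations` | relation/context data model, relation-table TSV dialect |
| `ctxabc.sentences` | annotated sentences (entity + clause spans) and their file format |
| `ctxabc.cooccur` | co-occurrence baseline: all gene pairs per sentence |
| `ctxabc.contexts` | clause-span detection (annotated or heuristic) and context extraction |
| `ctxabc.assign` | abstract-level context assignment |
| `ctxabc.hierarchy` | tree-position vocabularies, tree distance, element & context similarity |
| `ctxabc.abcmodel` | A–B–C path construction under the three models, B-entity dedup |
| `ctxabc.evaluation` | precision/recall/F over gold B-entity labels, threshold sweeps |
| `ctxabc.simulate` | synthetic corpora/hierarchies/gold labels with exact ground truth |
| `ctxabc.datasets` | small bundled reference datasets (worked abstract, verified B entities, toy hierarchies) |
| `ctxabc.cli` | `ctxabc` command-line interface |

## CLI

```sh
# generate a synthetic corpus with two planted chains (one context-matched)
ctxabc simulate --n-abstracts 12 --chain apoe:ins:mapt:1 --chain apoe:snca:mapt:0 \
    --seed 7 --outdir corpus/

# sentences -> co-occurrence relations with extracted contexts
ctxabc extract --sentences corpus/sentences.tsv --mode annotated --out relations.tsv

# abstract-level context assignment
ctxabc assign --relations relations.tsv --out assigned.tsv

# build paths under a model and threshold
ctxabc abc --relations relations.tsv --model context --a apoe --c mapt \
    --threshold 1.0 --vocab disease=corpus/hierarchy_disease.tsv \
    --vocab drug=corpus/hierarchy_drug.tsv --vocab cell=corpus/hierarchy_cell.tsv \
    --vocab organism=corpus/hierarchy_organism.tsv --out paths.tsv

# score the deduplicated B entities and sweep thresholds
ctxabc eval --paths paths.tsv --gold corpus/gold_apoe_mapt.tsv \
    --universe corpus/universe_apoe_mapt.txt
ctxabc sweep --relations relations.tsv --model context --a apoe --c mapt \
    --grid 0:1:0.1 --vocab disease=corpus/hierarchy_disease.tsv --gold corpus/gold_apoe_mapt.tsv

# or run everything from a plain-text config
ctxabc run --config pipeline.cfg
```

A pipeline config is `key: value` lines: `outdir`, `model`
(`cooccurrence|context|context-assignment`), `threshold`, `a`, `c`, one of
`sentences`/`relations`, optional `mode`, `vocab.<slot>`,
`max_distance.<slot>`, `gold`, `universe`, `seed`.

## File formats

* **Relation table** — UTF-8 TSV, header `PMID  Sentence_ID  Entity1
  Entity1OfficialSymbol  Entity2  Entity2OfficialSymbol  Negation  Voice
  Verb  Re_Type  CELL  DRUG  DISEASE  ORGANISM [ Origin]`; absent context
  slots hold the literal `NoData`, multi-valued slots are semicolon-joined.
* **Annotated sentences** — TSV with bracketed spans
  `[start:end:type:surface:symbol]` for entities and `[start:end:kind]` for
  clause spans.
* **Hierarchy** — `term<TAB>dotted.position` (MeSH-tree-number style), one
  row per term-position pair. Default maximum distances: cell 30, drug 14,
  disease 26, organism 12.
* **Gold labels** — `symbol<TAB>O|X`; recall universes are one symbol per
  line.

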