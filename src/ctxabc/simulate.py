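"""Synthetic corpora, hierarchies and gold labels with known ground truth.

The generator plants A–B–C chains into template abstracts: each chain
contributes an A–B sentence and a B–C sentence (in distinct abstracts) whose
context terms either agree exactly (a shared term, similarity 1) or fall in
different top-level hierarchy categories (similarity 0).  Non-planted filler
sentences use a disjoint gene namespace so planted chains are the only
A–C-relevant structure, making threshold-1 ground truth exact by
construction.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .evaluation import GoldLabels
from .hierarchy import HierarchyVocabulary, write_hierarchy
from .relations import CONTEXT_SLOTS, EntityMention, normalize_symbol
from .sentences import AnnotatedSentence, ClauseSpan, write_sentences

__all__ = [
    "PlantedChain",
    "SimulatedCorpus",
    "generate_hierarchy",
    "generate_corpus",
    "write_corpus",
]


@dataclass(frozen=True)
class PlantedChain:
    a: str
    b: str
    c: str
    context_match: bool = True

    @classmethod
    def coerce(cls, spec: "PlantedChain | Sequence") -> "PlantedChain":
        if isinstance(spec, PlantedChain):
            return spec
        a, b, c, match = spec
        return cls(normalize_symbol(a), normalize_symbol(b), normalize_symbol(c), bool(match))


@dataclass
class SimulatedCorpus:
    sentences: list[AnnotatedSentence]
    vocabularies: dict[str, HierarchyVocabulary]
    chains: tuple[PlantedChain, ...]
    #: (a, c) -> model name -> expected deduplicated B symbols at threshold 1.
    truth: dict[tuple[str, str], dict[str, tuple[str, ...]]]
    gold: dict[tuple[str, str], GoldLabels] = field(default_factory=dict)


def _tree_capacity(branching: int, depth: int) -> int:
    return sum(branching**level for level in range(depth + 1))


def generate_hierarchy(
    element_type: str,
    branching: int = 2,
    depth: int = 3,
    n_terms: int = 10,
    seed: int = 0,
    n_roots: int = 2,
) -> HierarchyVocabulary:
    """A random tree vocabulary of dotted positions; deterministic per seed.

    Positions are drawn without replacement from the complete ``n_roots``
    trees of the given branching factor and depth (root at depth 0), so all
    pairwise intra-root distances are at most ``2 * depth``.
    """
    if branching < 2 or depth < 2:
        raise ValueError("branching and depth must both be >= 2")
    capacity = n_roots * _tree_capacity(branching, depth)
    if n_terms > capacity:
        raise ValueError(
            f"n_terms={n_terms} exceeds tree capacity {capacity} "
            f"({n_roots} roots, branching {branching}, depth {depth})"
        )
    positions: list[tuple[str, ...]] = []
    for root_index in range(n_roots):
        level = [(f"{element_type[:1].upper()}{root_index + 1:02d}",)]
        positions.extend(level)
        for _ in range(depth):
            level = [pos + (str(child + 1),) for pos in level for child in range(branching)]
            positions.extend(level)
    rng = random.Random(seed)
    chosen = rng.sample(positions, n_terms)
    vocab = HierarchyVocabulary(element_type=element_type)
    for index, position in enumerate(chosen):
        vocab.add(f"{element_type}{index:03d}", position)
    return vocab


_FILLER_GENES = [f"fg{i:02d}" for i in range(30)]


def _make_sentence(
    pmid: str,
    sentence_id: int,
    gene1: str,
    gene2: str,
    extra_genes: Sequence[str] = (),
    context_term: Optional[str] = None,
    context_type: str = "disease",
) -> AnnotatedSentence:
    entities = []
    text = ""

    def mention(symbol: str, entity_type: str = "gene") -> str:
        nonlocal text
        surface = symbol.upper() if entity_type == "gene" else symbol
        start = len(text)
        text += surface
        entities.append(
            EntityMention(surface=surface, official_symbol=symbol,
                          entity_type=entity_type, span=(start, len(text)))
        )
        return surface

    mention(gene1)
    text += " interacts with "
    mention(gene2)
    for gene in extra_genes:
        text += " and "
        mention(gene)
    clause_spans = ()
    if context_term is not None:
        text += " "
        clause_start = len(text)
        text += "in "
        mention(context_term, context_type)
        text += " models"
        clause_spans = (ClauseSpan(clause_start, len(text), "prepositional"),)
    text += "."
    return AnnotatedSentence(pmid=pmid, sentence_id=sentence_id, text=text,
                             entities=entities, clause_spans=clause_spans)


def generate_corpus(
    n_abstracts: int,
    planted_chains: Sequence[PlantedChain | Sequence],
    context_rate: float = 0.3,
    seed: int = 0,
    contaminate: bool = False,
) -> SimulatedCorpus:
    """Build an annotated corpus with planted chains and exact ground truth.

    Chain i's A–B sentence goes to abstract 2i and its B–C sentence to
    abstract 2i+1, so every planted sentence sits in its own abstract.
    Matched chains share one context term; mismatched chains get terms from
    different top-level categories.  A ``context_rate`` fraction of
    non-planted abstracts carries decoy contexts on filler sentences; with
    ``contaminate=True`` decoys may also land in planted abstracts (always
    in a slot the planted context does not use, and with a distinct term per
    abstract, so the affected chains are provably disconnected at threshold
    1 in the context-assignment model and the ground truth stays exact).
    """
    if not 0.0 <= context_rate <= 1.0:
        raise ValueError("context_rate must lie in [0, 1]")
    chains = tuple(PlantedChain.coerce(c) for c in planted_chains)
    if n_abstracts < 2 * len(chains):
        raise ValueError(f"need at least {2 * len(chains)} abstracts for {len(chains)} chains")
    for chain in chains:
        for symbol in (chain.a, chain.b, chain.c):
            if symbol.startswith("fg"):
                raise ValueError("chain symbols must not use the filler namespace 'fg*'")

    rng = random.Random(seed)

    # Vocabularies: planted context terms are diseases; categories C01/C02
    # are unrelated, C03 hosts within-slot decoys.  The other three types
    # hold cross-slot decoy terms only.
    disease = HierarchyVocabulary(element_type="disease")
    matched_terms, mismatch_terms = [], []
    for i, chain in enumerate(chains):
        term = f"malady{i:03d}"
        disease.add(term, ("C01", "1", str(i + 1)))
        matched_terms.append(term)
        left, right = f"maladyl{i:03d}", f"maladyr{i:03d}"
        disease.add(left, ("C01", "9", str(i + 1)))
        disease.add(right, ("C02", "9", str(i + 1)))
        mismatch_terms.append((left, right))
    decoy_pools: dict[str, list[str]] = {"disease": []}
    for j in range(8):
        term = f"maladyx{j}"
        disease.add(term, ("C03", str(j + 1)))
        decoy_pools["disease"].append(term)
    vocabularies = {"disease": disease}
    for slot, prefix in (("cell", "cline"), ("drug", "compound"), ("organism", "critter")):
        vocab = HierarchyVocabulary(element_type=slot)
        pool = []
        for j in range(max(8, 2 * n_abstracts // 3)):
            term = f"{prefix}{j:03d}"
            vocab.add(term, (f"{slot[:1].upper()}01", str(j + 1)))
            pool.append(term)
        vocabularies[slot] = vocab
        decoy_pools[slot] = pool

    abstracts: list[list[AnnotatedSentence]] = [[] for _ in range(n_abstracts)]
    pmids = [f"{8000000 + i}" for i in range(n_abstracts)]
    planted_abstracts = set(range(2 * len(chains)))
    contaminated_abstracts: set[int] = set()

    def next_sid(index: int) -> int:
        return len(abstracts[index]) + 1

    # Planted sentences first (sentence 1 of their abstracts).
    for i, chain in enumerate(chains):
        if chain.context_match:
            ab_term = bc_term = matched_terms[i]
        else:
            ab_term, bc_term = mismatch_terms[i]
        ab_index, bc_index = 2 * i, 2 * i + 1
        abstracts[ab_index].append(
            _make_sentence(pmids[ab_index], next_sid(ab_index), chain.a, chain.b,
                           context_term=ab_term)
        )
        abstracts[bc_index].append(
            _make_sentence(pmids[bc_index], next_sid(bc_index), chain.b, chain.c,
                           context_term=bc_term)
        )

    # Filler sentences; decoy contexts by abstract, distinct term per abstract.
    for index in range(n_abstracts):
        in_planted = index in planted_abstracts
        n_filler = rng.randint(1, 2)
        decoy_here = rng.random() < context_rate and (contaminate or not in_planted)
        for k in range(n_filler):
            g1, g2 = rng.sample(_FILLER_GENES, 2)
            term, slot = None, "disease"
            if decoy_here and k == 0:
                # Planted abstracts only ever get cross-slot decoys, so the
                # planted disease slot is never silently absorbed.
                slot = rng.choice(("cell", "drug", "organism") if in_planted
                                  else ("cell", "drug", "organism", "disease"))
                pool = decoy_pools[slot]
                term = pool[index % len(pool)]
                if in_planted:
                    contaminated_abstracts.add(index)
            abstracts[index].append(
                _make_sentence(pmids[index], next_sid(index), g1, g2,
                               context_term=term, context_type=slot)
            )

    sentences = [s for abstract in abstracts for s in abstract]

    truth: dict[tuple[str, str], dict[str, tuple[str, ...]]] = {}
    gold: dict[tuple[str, str], GoldLabels] = {}
    for i, chain in enumerate(chains):
        key = (chain.a, chain.c)
        entry = truth.setdefault(
            key, {"cooccurrence": (), "context": (), "context_assignment": ()}
        )
        entry["cooccurrence"] += (chain.b,)
        if chain.context_match:
            entry["context"] += (chain.b,)
            if not ({2 * i, 2 * i + 1} & contaminated_abstracts):
                entry["context_assignment"] += (chain.b,)
    for key, entry in truth.items():
        for model in entry:
            entry[model] = tuple(dict.fromkeys(entry[model]))
        gold[key] = GoldLabels(
            relevant=frozenset(entry["context"]),
            universe=frozenset(entry["cooccurrence"]),
        )
    return SimulatedCorpus(sentences=sentences, vocabularies=vocabularies,
                           chains=chains, truth=truth, gold=gold)


def write_corpus(corpus: SimulatedCorpus, outdir: str | Path) -> dict[str, Path]:
    """Emit the corpus in the package's flat-file formats; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    sentences_path = outdir / "sentences.tsv"
    write_sentences(corpus.sentences, sentences_path)
    written["sentences"] = sentences_path
    for slot in CONTEXT_SLOTS:
        if slot in corpus.vocabularies:
            path = outdir / f"hierarchy_{slot}.tsv"
            write_hierarchy(corpus.vocabularies[slot], path)
            written[f"hierarchy_{slot}"] = path
    for (a, c), labels in corpus.gold.items():
        gold_path = outdir / f"gold_{a}_{c}.tsv"
        universe = sorted(labels.recall_universe)
        with gold_path.open("w", encoding="utf-8") as handle:
            for symbol in universe:
                mark = "O" if symbol in labels.relevant else "X"
                handle.write(f"{symbol}\t{mark}\n")
        written[f"gold_{a}_{c}"] = gold_path
        universe_path = outdir / f"universe_{a}_{c}.txt"
        universe_path.write_text("".join(f"{s}\n" for s in universe), encoding="utf-8")
        written[f"universe_{a}_{c}"] = universe_path
    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {f"{a}--{c}": {m: list(bs) for m, bs in entry.items()}
             for (a, c), entry in corpus.truth.items()},
            indent=2,
            sort_keys=True,
        ),
        encoding="utf-8",
    )
    written["truth"] = truth_path
    return written
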