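"""Biological-context extraction from conditioning clauses.

Context candidates live in prepositional or relative-adverb clauses.  Clause
spans are first-class input (annotated mode); a transparent token-scanning
heuristic is provided as a fallback so the stage works on raw text without a
constituency parser.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

from .relations import CONTEXT_SLOTS, ContextTuple, RelationRecord, normalize_term
from .sentences import AnnotatedSentence

__all__ = [
    "CONDITIONING_PREPOSITIONS",
    "RELATIVE_ADVERBS",
    "detect_context_spans",
    "extract_context",
    "apply_sentence_contexts",
    "extract_relations",
]

CONDITIONING_PREPOSITIONS = frozenset({"in", "within", "under", "during", "among", "from"})
RELATIVE_ADVERBS = frozenset({"where", "when", "while"})

#: Clause boundaries in heuristic mode: punctuation or a depth-0 coordinator.
_BOUNDARY_WORDS = frozenset({"and", "or", "but"})
_BOUNDARY_CHARS = ",.;"

_TOKEN = re.compile(r"\S+")
_OPENERS, _CLOSERS = "([{", ")]}"


def _char_depths(text: str) -> list[int]:
    """Bracket-nesting depth of each character position."""
    depths = []
    depth = 0
    for ch in text:
        if ch in _OPENERS:
            depths.append(depth)
            depth += 1
        elif ch in _CLOSERS:
            depth = max(0, depth - 1)
            depths.append(depth)
        else:
            depths.append(depth)
    return depths


def _heuristic_spans(text: str) -> list[tuple[int, int]]:
    """Maximal spans from a conditioning trigger word to the next boundary."""
    depths = _char_depths(text)
    tokens = [
        (m.start(), m.end(), m.group().strip(".,;:()[]{}“”\"'").lower())
        for m in _TOKEN.finditer(text)
    ]
    boundary_token_starts = {
        start for start, _, word in tokens if word in _BOUNDARY_WORDS and depths[start] == 0
    }
    spans: list[tuple[int, int]] = []
    for start, trigger_end, word in tokens:
        if depths[start] != 0:
            continue
        if word not in CONDITIONING_PREPOSITIONS and word not in RELATIVE_ADVERBS:
            continue
        if spans and start < spans[-1][1]:  # already inside a maximal span
            continue
        end = len(text)
        for pos in range(trigger_end, len(text)):
            if depths[pos] == 0 and (text[pos] in _BOUNDARY_CHARS or pos in boundary_token_starts):
                end = pos
                break
        end = len(text[:end].rstrip())
        if end > start:
            spans.append((start, end))
    return spans


def detect_context_spans(
    sentence: AnnotatedSentence, mode: str = "annotated"
) -> list[tuple[int, int]]:
    """Character intervals in which context candidates are searched.

    ``annotated`` returns the sentence's clause spans verbatim; ``heuristic``
    scans for spans opened by a conditioning preposition (in, within, under,
    during, among, from) or relative adverb (where, when, while) and closed
    at the next depth-0 comma/period/semicolon or coordinating conjunction.
    """
    if mode == "annotated":
        return [(c.start, c.end) for c in sentence.clause_spans]
    if mode == "heuristic":
        return _heuristic_spans(sentence.text)
    raise ValueError(f"unknown mode: {mode!r}")


def _overlaps(span: tuple[int, int], intervals: Sequence[tuple[int, int]]) -> bool:
    return any(span[0] < end and start < span[1] for start, end in intervals)


def extract_context(sentence: AnnotatedSentence, mode: str = "annotated") -> ContextTuple:
    """Collect typed context entities falling inside detected clause spans.

    Every cell/drug/disease/organism entity whose span intersects a context
    span contributes its normalized term to the matching slot; slots with no
    hit stay NoData.  Entities outside every span are never extracted.
    """
    spans = detect_context_spans(sentence, mode)
    slots: dict[str, set[str]] = {s: set() for s in CONTEXT_SLOTS}
    for entity in sentence.typed_entities(*CONTEXT_SLOTS):
        if entity.span is None or not _overlaps(entity.span, spans):
            continue
        slots[entity.entity_type].add(normalize_term(entity.official_symbol))
    return ContextTuple.from_terms(**{s: (v or None) for s, v in slots.items()})


def apply_sentence_contexts(
    records: Iterable[RelationRecord],
    sentences: Iterable[AnnotatedSentence],
    mode: str = "annotated",
) -> list[RelationRecord]:
    """Attach each sentence's extracted context to all its relations."""
    contexts = {
        (s.pmid, s.sentence_id): extract_context(s, mode) for s in sentences
    }
    out = []
    for record in records:
        ctx = contexts.get((record.pmid, record.sentence_id))
        if ctx is not None and not ctx.is_empty():
            out.append(record.with_context(record.context.merge(ctx)))
        else:
            out.append(record)
    return out


def extract_relations(
    sentences: Sequence[AnnotatedSentence],
    mode: str = "annotated",
    with_context: bool = True,
) -> list[RelationRecord]:
    """Full sentence-level extraction: co-occurrence pairs plus contexts."""
    from .cooccur import extract_cooccurrence_pairs

    records: list[RelationRecord] = []
    for sentence in sentences:
        records.extend(extract_cooccurrence_pairs(sentence))
    if with_context:
        records = apply_sentence_contexts(records, sentences, mode)
    return records
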