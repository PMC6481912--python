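"""Annotated sentences: the unit of extraction, plus flat-file IO.

The annotated-sentence file is a UTF-8 TSV with columns
``PMID  Sentence_ID  Text  Entities  Clauses`` where ``Entities`` is a
concatenation of bracketed spans ``[start:end:type:surface:symbol]`` and
``Clauses`` of ``[start:end:kind]`` with kind in
``{prepositional, relative_adverb}``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .relations import ENTITY_TYPES, EntityMention

__all__ = [
    "CLAUSE_KINDS",
    "AnnotatedSentence",
    "ClauseSpan",
    "read_sentences",
    "write_sentences",
]

CLAUSE_KINDS = ("prepositional", "relative_adverb")

SENTENCE_COLUMNS = ("PMID", "Sentence_ID", "Text", "Entities", "Clauses")

_BRACKETED = re.compile(r"\[([^\[\]]*)\]")


@dataclass(frozen=True)
class ClauseSpan:
    """A conditioning-clause character interval within a sentence."""

    start: int
    end: int
    kind: str = "prepositional"

    def __post_init__(self) -> None:
        if self.kind not in CLAUSE_KINDS:
            raise ValueError(f"unknown clause kind: {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid clause span: ({self.start}, {self.end})")


@dataclass(frozen=True)
class AnnotatedSentence:
    pmid: str
    sentence_id: int
    text: str
    entities: tuple[EntityMention, ...] = ()
    clause_spans: tuple[ClauseSpan, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entities", tuple(self.entities))
        object.__setattr__(self, "clause_spans", tuple(self.clause_spans))
        n = len(self.text)
        for entity in self.entities:
            if entity.span is not None and entity.span[1] > n:
                raise ValueError(
                    f"entity span {entity.span} outside sentence of length {n}"
                )
        for clause in self.clause_spans:
            if clause.end > n:
                raise ValueError(f"clause span ({clause.start}, {clause.end}) outside text")

    def typed_entities(self, *types: str) -> tuple[EntityMention, ...]:
        return tuple(e for e in self.entities if e.entity_type in types)


def _format_entities(entities: Sequence[EntityMention]) -> str:
    parts = []
    for e in entities:
        if e.span is None:
            raise ValueError(f"entity {e.official_symbol!r} has no span; cannot serialize")
        for text in (e.surface, e.official_symbol):
            if ":" in text or "[" in text or "]" in text:
                raise ValueError(f"cannot serialize text containing ':[]': {text!r}")
        parts.append(f"[{e.span[0]}:{e.span[1]}:{e.entity_type}:{e.surface}:{e.official_symbol}]")
    return "".join(parts)


def _parse_entities(cell: str) -> tuple[EntityMention, ...]:
    out = []
    for chunk in _BRACKETED.findall(cell):
        start, end, etype, surface, symbol = chunk.split(":", 4)
        out.append(
            EntityMention(
                surface=surface,
                official_symbol=symbol,
                entity_type=etype,
                span=(int(start), int(end)),
            )
        )
    return tuple(out)


def _format_clauses(clauses: Sequence[ClauseSpan]) -> str:
    return "".join(f"[{c.start}:{c.end}:{c.kind}]" for c in clauses)


def _parse_clauses(cell: str) -> tuple[ClauseSpan, ...]:
    out = []
    for chunk in _BRACKETED.findall(cell):
        start, end, kind = chunk.split(":", 2)
        out.append(ClauseSpan(int(start), int(end), kind))
    return tuple(out)


def read_sentences(path: str | Path) -> list[AnnotatedSentence]:
    path = Path(path)
    sentences = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for column in SENTENCE_COLUMNS:
            if column not in (reader.fieldnames or []):
                raise ValueError(f"{path}: missing required column {column!r}")
        for row in reader:
            sentences.append(
                AnnotatedSentence(
                    pmid=row["PMID"].strip(),
                    sentence_id=int(row["Sentence_ID"]),
                    text=row["Text"],
                    entities=_parse_entities(row["Entities"] or ""),
                    clause_spans=_parse_clauses(row["Clauses"] or ""),
                )
            )
    return sentences


def write_sentences(sentences: Sequence[AnnotatedSentence], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SENTENCE_COLUMNS)
        for s in sentences:
            writer.writerow(
                [
                    s.pmid,
                    str(s.sentence_id),
                    s.text,
                    _format_entities(s.entities),
                    _format_clauses(s.clause_spans),
                ]
            )
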