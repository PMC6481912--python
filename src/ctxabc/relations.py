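"""Entity-relation data model and tab-separated relation-table IO.

A relation table has one row per extracted entity relation with provenance
(PMID, sentence id), the two entity mentions (surface form and official
symbol), verb metadata, and a four-slot biological context
(cell / drug / disease / organism).  Unidentified context slots hold the
literal sentinel ``NoData``; multi-valued slots are semicolon-joined.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ENTITY_TYPES",
    "CONTEXT_SLOTS",
    "NODATA",
    "RELATION_COLUMNS",
    "EntityMention",
    "ContextTuple",
    "RelationRecord",
    "RelationTableError",
    "normalize_symbol",
    "normalize_term",
    "read_relation_table",
    "write_relation_table",
]

ENTITY_TYPES = ("gene", "cell", "drug", "disease", "organism")

#: The four biological context element types, in column order.
CONTEXT_SLOTS = ("cell", "drug", "disease", "organism")

#: Literal cell value marking an unidentified context element.
NODATA = "NoData"

RELATION_COLUMNS = (
    "PMID",
    "Sentence_ID",
    "Entity1",
    "Entity1OfficialSymbol",
    "Entity2",
    "Entity2OfficialSymbol",
    "Negation",
    "Voice",
    "Verb",
    "Re_Type",
    "CELL",
    "DRUG",
    "DISEASE",
    "ORGANISM",
)

#: Optional trailing column recording how a row was produced.
ORIGIN_COLUMN = "Origin"

ORIGINS = ("verb_based", "cooccurrence", "assigned")

_WS = re.compile(r"\s+")


class RelationTableError(ValueError):
    """Raised for schema or parse failures in relation-table files."""


def normalize_symbol(surface: str, dictionary: Optional[Mapping[str, str]] = None) -> str:
    """Map a surface form to its official symbol.

    The dictionary maps lowercase surfaces to official symbols; on a miss the
    lowercased, whitespace-trimmed surface itself is the symbol.  Idempotent.
    """
    key = surface.strip().lower()
    if not key:
        raise ValueError("cannot normalize an empty surface form")
    if dictionary:
        hit = dictionary.get(key)
        if hit is not None:
            return hit.strip().lower()
    return key


def normalize_term(text: str) -> str:
    """Normalize a context term: lowercase with all whitespace removed.

    ``"transgenic mouse" -> "transgenicmouse"``.  Hierarchy files are
    normalized with the same function on load, so extracted terms and
    vocabulary terms always compare in one canonical form.
    """
    return _WS.sub("", text.strip().lower())


@dataclass(frozen=True)
class EntityMention:
    """A typed entity mention, optionally anchored to a character span."""

    surface: str
    official_symbol: str
    entity_type: str = "gene"
    span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.official_symbol:
            raise ValueError("official_symbol must be non-empty")
        if self.official_symbol != self.official_symbol.lower():
            object.__setattr__(self, "official_symbol", self.official_symbol.lower())
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type: {self.entity_type!r}")
        if self.span is not None:
            start, end = self.span
            if not (0 <= start < end):
                raise ValueError(f"invalid span: {self.span!r}")


@dataclass(frozen=True)
class ContextTuple:
    """The four-slot biological context of an entity relation.

    Each slot is either ``None`` (NoData) or a non-empty frozenset of
    normalized hierarchy terms.
    """

    cell: Optional[frozenset[str]] = None
    drug: Optional[frozenset[str]] = None
    disease: Optional[frozenset[str]] = None
    organism: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        for slot in CONTEXT_SLOTS:
            value = getattr(self, slot)
            if value is None:
                continue
            value = frozenset(value)
            if not value or any(not t for t in value):
                raise ValueError(f"context slot {slot!r} must be None or a non-empty term set")
            object.__setattr__(self, slot, value)

    @classmethod
    def from_terms(cls, **slots: Iterable[str] | str | None) -> "ContextTuple":
        """Build a tuple from per-slot terms (string or iterable of strings)."""
        kwargs = {}
        for slot, value in slots.items():
            if value is None:
                kwargs[slot] = None
            elif isinstance(value, str):
                kwargs[slot] = frozenset([value])
            else:
                kwargs[slot] = frozenset(value)
        return cls(**kwargs)

    def slot(self, name: str) -> Optional[frozenset[str]]:
        if name not in CONTEXT_SLOTS:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def element_count(self) -> int:
        """Number of identified (non-NoData) slots, 0..4."""
        return sum(getattr(self, s) is not None for s in CONTEXT_SLOTS)

    def is_empty(self) -> bool:
        return self.element_count == 0

    def merge(self, other: "ContextTuple") -> "ContextTuple":
        """Per-slot union of two contexts (NoData slots contribute nothing)."""
        kwargs = {}
        for slot in CONTEXT_SLOTS:
            mine, theirs = getattr(self, slot), getattr(other, slot)
            if mine is None:
                kwargs[slot] = theirs
            elif theirs is None:
                kwargs[slot] = mine
            else:
                kwargs[slot] = mine | theirs
        return ContextTuple(**kwargs)


EMPTY_CONTEXT = ContextTuple()


@dataclass(frozen=True)
class RelationRecord:
    """One extracted entity relation plus its biological context."""

    pmid: str
    sentence_id: int
    entity1: EntityMention
    entity2: EntityMention
    negation: str = "POSITIVE"
    voice: str = "ACTIVE"
    verb: str = ""
    re_type: str = ""
    context: ContextTuple = field(default_factory=ContextTuple)
    origin: str = "verb_based"

    def __post_init__(self) -> None:
        if self.negation not in ("POSITIVE", "NEGATIVE"):
            raise ValueError(f"negation must be POSITIVE or NEGATIVE, got {self.negation!r}")
        if self.voice not in ("ACTIVE", "PASSIVE"):
            raise ValueError(f"voice must be ACTIVE or PASSIVE, got {self.voice!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin: {self.origin!r}")
        if self.entity1.official_symbol == self.entity2.official_symbol:
            raise ValueError(
                f"self-relation: both endpoints are {self.entity1.official_symbol!r}"
            )

    @property
    def symbols(self) -> tuple[str, str]:
        return (self.entity1.official_symbol, self.entity2.official_symbol)

    def partner(self, symbol: str) -> Optional[str]:
        """The other endpoint if ``symbol`` is one of the two, else None."""
        s1, s2 = self.symbols
        if symbol == s1:
            return s2
        if symbol == s2:
            return s1
        return None

    def with_context(self, context: ContextTuple, origin: Optional[str] = None) -> "RelationRecord":
        return replace(self, context=context, origin=origin or self.origin)


def _format_slot(value: Optional[frozenset[str]]) -> str:
    if value is None:
        return NODATA
    return ";".join(sorted(value))


def _parse_slot(cell: str) -> Optional[frozenset[str]]:
    cell = cell.strip()
    if not cell or cell == NODATA:
        return None
    terms = frozenset(normalize_term(t) for t in cell.split(";") if t.strip())
    return terms or None


def read_relation_table(path: str | Path, strict: bool = True) -> list[RelationRecord]:
    """Read a relation table, returning records in file order.

    Raises :class:`RelationTableError` naming the column when a required
    column is missing, or (in strict mode) naming the row when Sentence_ID
    is not an integer.
    """
    path = Path(path)
    records: list[RelationRecord] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        for column in RELATION_COLUMNS:
            if column not in header:
                raise RelationTableError(f"{path}: missing required column {column!r}")
        has_origin = ORIGIN_COLUMN in header
        for lineno, row in enumerate(reader, start=2):
            raw_sid = (row["Sentence_ID"] or "").strip()
            try:
                sentence_id = int(raw_sid)
            except ValueError:
                if strict:
                    raise RelationTableError(
                        f"{path}: row {lineno}: non-integer Sentence_ID {raw_sid!r}"
                    ) from None
                sentence_id = -1
            context = ContextTuple(
                cell=_parse_slot(row["CELL"]),
                drug=_parse_slot(row["DRUG"]),
                disease=_parse_slot(row["DISEASE"]),
                organism=_parse_slot(row["ORGANISM"]),
            )
            origin = (row.get(ORIGIN_COLUMN) or "verb_based").strip() if has_origin else "verb_based"
            records.append(
                RelationRecord(
                    pmid=row["PMID"].strip(),
                    sentence_id=sentence_id,
                    entity1=EntityMention(
                        surface=row["Entity1"].strip(),
                        official_symbol=normalize_symbol(row["Entity1OfficialSymbol"]),
                    ),
                    entity2=EntityMention(
                        surface=row["Entity2"].strip(),
                        official_symbol=normalize_symbol(row["Entity2OfficialSymbol"]),
                    ),
                    negation=row["Negation"].strip().upper(),
                    voice=row["Voice"].strip().upper(),
                    verb=row["Verb"].strip(),
                    re_type=row["Re_Type"].strip(),
                    context=context,
                    origin=origin or "verb_based",
                )
            )
    return records


def write_relation_table(
    records: Sequence[RelationRecord],
    path: str | Path,
    include_origin: bool = True,
) -> None:
    """Write records in the same dialect :func:`read_relation_table` accepts."""
    path = Path(path)
    columns = RELATION_COLUMNS + ((ORIGIN_COLUMN,) if include_origin else ())
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for record in records:
            row = [
                record.pmid,
                str(record.sentence_id),
                record.entity1.surface,
                record.entity1.official_symbol,
                record.entity2.surface,
                record.entity2.official_symbol,
                record.negation,
                record.voice,
                record.verb,
                record.re_type,
                _format_slot(record.context.cell),
                _format_slot(record.context.drug),
                _format_slot(record.context.disease),
                _format_slot(record.context.organism),
            ]
            if include_origin:
                row.append(record.origin)
            writer.writerow(row)
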