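"""A–B–C path construction under the three discovery models.

Closed discovery: A and C are fixed, and every relation containing A with
some partner B is joined to every relation containing B with partner C
(undirected matching on official symbols).  The plain co-occurrence model
joins unconditionally; the context models additionally require the context
similarity of the two relations to reach a threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .assign import assign_contexts
from .hierarchy import HierarchyVocabulary, context_similarity
from .relations import (
    CONTEXT_SLOTS,
    ContextTuple,
    RelationRecord,
    normalize_symbol,
)
from .relations import NODATA

__all__ = ["MODELS", "ABCPath", "build_paths", "dedup_b_entities",
           "read_path_table", "write_path_table"]

MODELS = ("cooccurrence", "context", "context_assignment")

#: Float guard so a score of exactly 1.0 passes a threshold of 1.
_EPS = 1e-9


@dataclass(frozen=True)
class ABCPath:
    a: str
    b: str
    c: str
    ab_relation: Optional[RelationRecord] = None
    bc_relation: Optional[RelationRecord] = None
    ab_context: ContextTuple = ContextTuple()
    bc_context: ContextTuple = ContextTuple()
    similarity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.a == self.b or self.b == self.c:
            raise ValueError(f"degenerate path {self.a}-{self.b}-{self.c}")


def build_paths(
    relations: Sequence[RelationRecord],
    a: str,
    c: str,
    model: str = "context",
    threshold: float = 1.0,
    vocabs: Optional[Mapping[str, HierarchyVocabulary]] = None,
    apply_assignment: bool = False,
) -> list[ABCPath]:
    """All A–B–C paths surviving the model's context gate.

    ``model`` is one of ``cooccurrence`` (no gate), ``context`` (relations
    without any context are dropped, then pairs must score >= threshold), or
    ``context_assignment`` (like ``context`` but expects assignment to have
    been applied; pass ``apply_assignment=True`` to run it here).  Paths are
    ordered by (B symbol, A–B PMID, B–C PMID); one path is emitted per
    relation-instance pair, so identical triples with different provenance
    repeat.  Deduplication happens at the B-entity level only.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model: {model!r}")
    a = normalize_symbol(a)
    c = normalize_symbol(c)
    if a == c:
        raise ValueError("closed discovery requires distinct A and C entities")
    if model == "context_assignment" and apply_assignment:
        relations = assign_contexts(list(relations))
    if model == "context":
        relations = [r for r in relations if not r.context.is_empty()]

    ab_legs: list[tuple[str, RelationRecord]] = []
    bc_legs: dict[str, list[RelationRecord]] = {}
    for record in relations:
        partner = record.partner(a)
        if partner is not None and partner != c:
            ab_legs.append((partner, record))
        partner = record.partner(c)
        if partner is not None and partner != a:
            bc_legs.setdefault(partner, []).append(record)

    gated = model in ("context", "context_assignment")
    if gated and vocabs is None:
        raise ValueError(f"model {model!r} requires hierarchy vocabularies")
    paths = []
    for b, ab in ab_legs:
        for bc in bc_legs.get(b, ()):
            similarity = None
            if gated:
                similarity = context_similarity(ab.context, bc.context, vocabs)
                if similarity < threshold - _EPS:
                    continue
            paths.append(
                ABCPath(
                    a=a, b=b, c=c,
                    ab_relation=ab, bc_relation=bc,
                    ab_context=ab.context, bc_context=bc.context,
                    similarity=similarity,
                )
            )
    paths.sort(key=lambda p: (p.b,
                              p.ab_relation.pmid if p.ab_relation else "",
                              p.bc_relation.pmid if p.bc_relation else ""))
    return paths


def dedup_b_entities(paths: Sequence[ABCPath]) -> list[str]:
    """Unique B symbols in first-appearance order."""
    seen = set()
    out = []
    for path in paths:
        if path.b not in seen:
            seen.add(path.b)
            out.append(path.b)
    return out


PATH_COLUMNS = (
    "EntityA", "EntityB", "EntityC",
    "AB_CELL", "AB_DRUG", "AB_DISEASE", "AB_ORGANISM",
    "BC_CELL", "BC_DRUG", "BC_DISEASE", "BC_ORGANISM",
    "Similarity",
)


def _slot_cell(ctx: ContextTuple, slot: str) -> str:
    value = ctx.slot(slot)
    return NODATA if value is None else ";".join(sorted(value))


def _parse_slot_cell(cell: str) -> Optional[frozenset[str]]:
    from .relations import normalize_term

    cell = (cell or "").strip()
    if not cell or cell in (NODATA, "·", "."):
        return None
    return frozenset(normalize_term(t) for t in cell.split(";") if t.strip()) or None


def write_path_table(paths: Sequence[ABCPath], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PATH_COLUMNS)
        for p in paths:
            row = [p.a, p.b, p.c]
            row += [_slot_cell(p.ab_context, s) for s in CONTEXT_SLOTS]
            row += [_slot_cell(p.bc_context, s) for s in CONTEXT_SLOTS]
            row.append("" if p.similarity is None else f"{p.similarity:.6f}")
            writer.writerow(row)


def read_path_table(path: str | Path) -> list[ABCPath]:
    path = Path(path)
    paths = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for column in PATH_COLUMNS:
            if column not in (reader.fieldnames or []):
                raise ValueError(f"{path}: missing required column {column!r}")
        for row in reader:
            ab_ctx = ContextTuple(**{
                s: _parse_slot_cell(row[f"AB_{s.upper()}"]) for s in CONTEXT_SLOTS
            })
            bc_ctx = ContextTuple(**{
                s: _parse_slot_cell(row[f"BC_{s.upper()}"]) for s in CONTEXT_SLOTS
            })
            sim = (row.get("Similarity") or "").strip()
            paths.append(
                ABCPath(
                    a=normalize_symbol(row["EntityA"]),
                    b=normalize_symbol(row["EntityB"]),
                    c=normalize_symbol(row["EntityC"]),
                    ab_context=ab_ctx,
                    bc_context=bc_ctx,
                    similarity=float(sim) if sim else None,
                )
            )
    return paths
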