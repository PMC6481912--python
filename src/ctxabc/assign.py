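"""Abstract-level context assignment.

All relations extracted from one abstract receive the same combined
biological context: the per-slot union of every context extracted anywhere
in that abstract.  Abstracts with no context at all pass through unchanged.
"""

from __future__ import annotations

from typing import Iterable

from .relations import EMPTY_CONTEXT, ContextTuple, RelationRecord

__all__ = ["assign_contexts", "combined_context"]


def combined_context(records: Iterable[RelationRecord]) -> ContextTuple:
    """Per-slot union of the contexts of a group of records."""
    combined = EMPTY_CONTEXT
    for record in records:
        combined = combined.merge(record.context)
    return combined


def assign_contexts(records: list[RelationRecord]) -> list[RelationRecord]:
    """Propagate each abstract's combined context to all its relations.

    Records that previously carried no context are re-tagged with
    ``origin="assigned"``.  Idempotent, and never removes a context value:
    per slot, each output context is a superset of the input.
    """
    by_pmid: dict[str, ContextTuple] = {}
    for record in records:
        by_pmid[record.pmid] = by_pmid.get(record.pmid, EMPTY_CONTEXT).merge(record.context)
    out = []
    for record in records:
        combined = by_pmid[record.pmid]
        if combined.is_empty():
            out.append(record)
        elif record.context == combined:
            out.append(record)
        else:
            origin = "assigned" if record.context.is_empty() else record.origin
            out.append(record.with_context(combined, origin=origin))
    return out
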