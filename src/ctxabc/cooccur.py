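"""Co-occurrence relation extraction: all gene pairs sharing a sentence."""

from __future__ import annotations

from .relations import RelationRecord
from .sentences import AnnotatedSentence

__all__ = ["extract_cooccurrence_pairs"]


def extract_cooccurrence_pairs(sentence: AnnotatedSentence) -> list[RelationRecord]:
    """One relation per unordered pair of distinct gene symbols in a sentence.

    Duplicate mentions of a symbol collapse before pairing (pairs are
    symbol-level); entity1 is the earlier mention in the sentence.  Emitted
    records carry no verb, relation type ``COOCCUR``, POSITIVE/ACTIVE
    defaults, and an all-NoData context.
    """
    seen: dict[str, tuple[int, object]] = {}
    for position, entity in enumerate(sentence.typed_entities("gene")):
        key = entity.span[0] if entity.span is not None else position
        if entity.official_symbol not in seen or key < seen[entity.official_symbol][0]:
            seen[entity.official_symbol] = (key, entity)
    genes = [entity for _, entity in sorted(seen.values(), key=lambda pair: pair[0])]
    records = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            records.append(
                RelationRecord(
                    pmid=sentence.pmid,
                    sentence_id=sentence.sentence_id,
                    entity1=genes[i],
                    entity2=genes[j],
                    verb="",
                    re_type="COOCCUR",
                    origin="cooccurrence",
                )
            )
    return records
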