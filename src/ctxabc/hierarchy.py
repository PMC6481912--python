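"""Tree-position vocabularies and context-similarity scoring.

Each context element type (cell, drug, disease, organism) has a vocabulary
mapping terms to dotted tree positions (MeSH-tree-number style, e.g.
``C10.228.140.380``) and a maximum-distance normalizer.  Element similarity
is ``1 - distance / max_distance`` over the shortest path through the
deepest common prefix; the aggregate context similarity is the sum of
per-slot similarities over slots identified in both contexts, normalized
cosine-style by ``sqrt(n1 * n2)`` where ``n_i`` counts identified slots.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .relations import CONTEXT_SLOTS, ContextTuple, normalize_term

__all__ = [
    "DEFAULT_MAX_DISTANCES",
    "UNRELATED",
    "HierarchyVocabulary",
    "UnknownTermError",
    "load_hierarchy",
    "write_hierarchy",
    "tree_distance",
    "element_similarity",
    "context_similarity",
]

#: Per-element-type maximum hierarchy distances used as normalizers.
DEFAULT_MAX_DISTANCES = {"cell": 30, "drug": 14, "disease": 26, "organism": 12}

_POSITION = re.compile(r"^[A-Za-z0-9\-]+(\.[A-Za-z0-9\-]+)*$")


class _Unrelated:
    """Sentinel distance for terms in different top-level categories."""

    _instance: Optional["_Unrelated"] = None

    def __new__(cls) -> "_Unrelated":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "UNRELATED"


UNRELATED = _Unrelated()

Distance = Union[int, _Unrelated]


class UnknownTermError(KeyError):
    def __init__(self, term: str, element_type: str):
        super().__init__(f"term {term!r} not in the {element_type} vocabulary")
        self.term = term


def parse_position(text: str) -> tuple[str, ...]:
    text = text.strip()
    if not _POSITION.match(text):
        raise ValueError(f"malformed tree position: {text!r}")
    return tuple(text.split("."))


@dataclass
class HierarchyVocabulary:
    """term -> tree positions for one context element type."""

    element_type: str
    positions: dict[str, frozenset[tuple[str, ...]]] = field(default_factory=dict)
    max_distance: int = 0

    def __post_init__(self) -> None:
        if self.element_type not in CONTEXT_SLOTS:
            raise ValueError(f"unknown element type: {self.element_type!r}")
        if self.max_distance <= 0:
            self.max_distance = DEFAULT_MAX_DISTANCES[self.element_type]

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def lookup(self, term: str) -> frozenset[tuple[str, ...]]:
        key = normalize_term(term)
        try:
            return self.positions[key]
        except KeyError:
            raise UnknownTermError(term, self.element_type) from None

    def add(self, term: str, position: str | tuple[str, ...]) -> None:
        if isinstance(position, str):
            position = parse_position(position)
        key = normalize_term(term)
        self.positions[key] = self.positions.get(key, frozenset()) | {tuple(position)}

    @property
    def terms(self) -> list[str]:
        return sorted(self.positions)


def load_hierarchy(
    path: str | Path,
    element_type: str,
    max_distance: Optional[int] = None,
) -> HierarchyVocabulary:
    """Read a two-column flat file: ``term<TAB>dotted.position`` per row.

    Terms are normalized (lowercase, whitespace stripped) so they compare
    identically with extracted context terms.  Malformed positions raise a
    ValueError carrying the line number.
    """
    path = Path(path)
    vocab = HierarchyVocabulary(element_type=element_type, max_distance=max_distance or 0)
    with path.open(newline="", encoding="utf-8") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'term<TAB>position'")
            try:
                vocab.add(row[0], parse_position(row[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return vocab


def write_hierarchy(vocab: HierarchyVocabulary, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for term in sorted(vocab.positions):
            for position in sorted(vocab.positions[term]):
                writer.writerow([term, ".".join(position)])


def _pair_distance(p1: Sequence[str], p2: Sequence[str]) -> Distance:
    lcp = 0
    for a, b in zip(p1, p2):
        if a != b:
            break
        lcp += 1
    if lcp == 0:
        return UNRELATED
    return (len(p1) - lcp) + (len(p2) - lcp)


def tree_distance(term1: str, term2: str, vocab: HierarchyVocabulary) -> Distance:
    """Minimum edge-path length between two terms through a common prefix.

    Positions whose dotted paths share no leading segment live in different
    top-level categories and are UNRELATED.  Identical positions have
    distance 0.  The minimum over all position pairs is returned (terms may
    occupy several positions in a poly-hierarchy).
    """
    best: Distance = UNRELATED
    for p1 in vocab.lookup(term1):
        for p2 in vocab.lookup(term2):
            d = _pair_distance(p1, p2)
            if d is UNRELATED:
                continue
            if best is UNRELATED or d < best:
                best = d
    return best


Terms = Union[str, Iterable[str]]


def element_similarity(terms1: Terms, terms2: Terms, vocab: HierarchyVocabulary) -> float:
    """``1 - distance / max_distance``, clamped to [0, 1].

    UNRELATED terms, and distances at or beyond the maximum, score 0.
    Set-valued inputs score as the maximum over cross pairs.
    """
    set1 = [terms1] if isinstance(terms1, str) else list(terms1)
    set2 = [terms2] if isinstance(terms2, str) else list(terms2)
    best = 0.0
    for t1 in set1:
        for t2 in set2:
            d = tree_distance(t1, t2, vocab)
            if d is UNRELATED:
                continue
            best = max(best, max(0.0, 1.0 - d / vocab.max_distance))
    return best


def context_similarity(
    ctx1: ContextTuple,
    ctx2: ContextTuple,
    vocabs: Mapping[str, HierarchyVocabulary],
    shared_counts: bool = False,
) -> float:
    """Aggregate similarity of two biological contexts, in [0, 1].

    Slots identified in both contexts contribute their element similarity to
    the numerator; slots NoData on either side contribute nothing.  The
    denominator is ``sqrt(n1 * n2)`` with ``n_i`` the number of identified
    slots of context i (``shared_counts=True`` counts only mutually
    identified slots instead).  Either context empty scores 0.
    """
    shared = [
        slot
        for slot in CONTEXT_SLOTS
        if ctx1.slot(slot) is not None and ctx2.slot(slot) is not None
    ]
    if shared_counts:
        n1 = n2 = len(shared)
    else:
        n1, n2 = ctx1.element_count, ctx2.element_count
    if n1 == 0 or n2 == 0:
        return 0.0
    numerator = 0.0
    for slot in shared:
        vocab = vocabs.get(slot)
        if vocab is None:
            raise KeyError(f"no vocabulary supplied for element type {slot!r}")
        numerator += element_similarity(ctx1.slot(slot), ctx2.slot(slot), vocab)
    return numerator / math.sqrt(n1 * n2)
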