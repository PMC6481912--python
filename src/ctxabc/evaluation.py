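"""Precision/recall scoring of B entities and threshold sweeps."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .abcmodel import build_paths, dedup_b_entities
from .hierarchy import HierarchyVocabulary
from .relations import RelationRecord, normalize_symbol

__all__ = [
    "GoldLabels",
    "EvaluationResult",
    "SweepRow",
    "evaluate",
    "threshold_sweep",
    "read_verification_table",
    "read_symbol_list",
]


@dataclass(frozen=True)
class GoldLabels:
    """Relevance labels: the relevant set, plus an assumed-complete universe
    used as the recall denominator (defaults to the relevant set)."""

    relevant: frozenset[str]
    universe: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "relevant", frozenset(self.relevant))
        if self.universe is not None:
            object.__setattr__(self, "universe", frozenset(self.universe))
            if not self.relevant <= self.universe:
                raise ValueError("relevant symbols must be a subset of the universe")

    @property
    def recall_universe(self) -> frozenset[str]:
        return self.universe if self.universe is not None else self.relevant


@dataclass(frozen=True)
class EvaluationResult:
    precision: Optional[float]  # None (NA) when nothing was predicted
    recall: Optional[float]
    f_measure: float
    n_predicted: int
    n_true_positive: int


def evaluate(predicted: Sequence[str], gold: GoldLabels) -> EvaluationResult:
    """Counting precision/recall over deduplicated predicted symbols.

    precision = |predicted ∩ relevant| / |predicted| (NA when no
    predictions); recall = |predicted ∩ relevant| / |universe|; F is the
    harmonic mean, 0 when either side is 0 or NA.
    """
    unique = list(dict.fromkeys(normalize_symbol(s) for s in predicted))
    tp = sum(1 for s in unique if s in gold.relevant)
    precision = tp / len(unique) if unique else None
    universe = gold.recall_universe
    recall = tp / len(universe) if universe else None
    if precision and recall:
        f_measure = 2 * precision * recall / (precision + recall)
    else:
        f_measure = 0.0
    return EvaluationResult(precision, recall, f_measure, len(unique), tp)


@dataclass(frozen=True)
class SweepRow:
    threshold: float
    n_paths: int
    n_b: int
    precision: Optional[float]
    recall: Optional[float]
    f_measure: float


def threshold_sweep(
    relations: Sequence[RelationRecord],
    a: str,
    c: str,
    model: str,
    thresholds: Sequence[float],
    vocabs: Optional[Mapping[str, HierarchyVocabulary]] = None,
    gold: Optional[GoldLabels] = None,
) -> list[SweepRow]:
    """Path/B-entity counts (and scores, when gold labels are given) per
    ascending threshold.  Counts are non-increasing in the threshold."""
    rows = []
    for threshold in thresholds:
        paths = build_paths(relations, a, c, model=model, threshold=threshold, vocabs=vocabs)
        b_entities = dedup_b_entities(paths)
        if gold is not None:
            result = evaluate(b_entities, gold)
            rows.append(SweepRow(threshold, len(paths), len(b_entities),
                                 result.precision, result.recall, result.f_measure))
        else:
            rows.append(SweepRow(threshold, len(paths), len(b_entities), None, None, 0.0))
    return rows


def read_verification_table(path: str | Path) -> tuple[list[str], GoldLabels]:
    """Read a ``symbol<TAB>O|X`` relevance table.

    Returns the symbols in file order (the prediction list) and GoldLabels
    whose relevant set holds the O-marked symbols.
    """
    path = Path(path)
    symbols: list[str] = []
    relevant = set()
    with path.open(newline="", encoding="utf-8") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or not row[0].strip():
                continue
            if len(row) < 2 or row[1].strip().upper() not in ("O", "X"):
                raise ValueError(f"{path}:{lineno}: expected 'symbol<TAB>O|X'")
            symbol = normalize_symbol(row[0])
            symbols.append(symbol)
            if row[1].strip().upper() == "O":
                relevant.add(symbol)
    return symbols, GoldLabels(relevant=frozenset(relevant))


def read_symbol_list(path: str | Path) -> list[str]:
    """One symbol per line (universe files, prediction lists)."""
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        return [normalize_symbol(line) for line in handle if line.strip()]
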