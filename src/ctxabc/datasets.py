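"""Loaders for the small reference datasets bundled with the package.

These plain-text files cover one worked abstract (PMID 23829269) with its
annotated sentences and extracted relations, a 19-path APOE–MAPT result
table with the relation table that generates it, expert-verified B-entity
label tables for two closed-discovery cases, and toy hierarchy files (MeSH /
DrugBank / KEGG stand-ins) resolving every context term they mention.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .abcmodel import ABCPath, read_path_table
from .evaluation import GoldLabels, read_verification_table
from .hierarchy import HierarchyVocabulary, load_hierarchy
from .relations import RelationRecord, read_relation_table
from .sentences import AnnotatedSentence, read_sentences

__all__ = [
    "data_path",
    "load_demo_abstract",
    "load_demo_relations",
    "load_reference_vocabularies",
    "load_printed_paths",
    "load_path_relations",
    "load_verified_b_entities",
]

#: Closed-discovery cases with bundled verification tables, keyed by
#: "<a>-<c>" pair then model name.
VERIFICATION_FILES = {
    ("apoe-mapt", "context"): "bentities_apoe_mapt_context.tsv",
    ("apoe-mapt", "context_assignment"): "bentities_apoe_mapt_assignment.tsv",
    ("fus-tardbp", "context"): "bentities_fus_tardbp_context.tsv",
    ("fus-tardbp", "context_assignment"): "bentities_fus_tardbp_assignment.tsv",
}


def data_path(name: str) -> Path:
    path = Path(str(resources.files("ctxabc").joinpath("data", name)))
    if not path.is_file():
        raise FileNotFoundError(f"no bundled dataset named {name!r}")
    return path


def load_demo_abstract() -> list[AnnotatedSentence]:
    """Annotated sentences 1 and 8 of the worked abstract (PMID 23829269)."""
    return read_sentences(data_path("sentences_pmid23829269.tsv"))


def load_demo_relations() -> list[RelationRecord]:
    """The two verb-based relations of the worked abstract, with the
    sentence-level contexts already attached."""
    return read_relation_table(data_path("relations_pmid23829269.tsv"))


def load_reference_vocabularies() -> dict[str, HierarchyVocabulary]:
    return {
        element_type: load_hierarchy(data_path(f"hierarchy_{element_type}.tsv"), element_type)
        for element_type in ("cell", "drug", "disease", "organism")
    }


def load_printed_paths(pair: str = "apoe-mapt") -> list[ABCPath]:
    """The published 19-path context-model result table for APOE–MAPT."""
    if pair != "apoe-mapt":
        raise KeyError(f"no printed path table for {pair!r}")
    return read_path_table(data_path("paths_apoe_mapt.tsv"))


def load_path_relations(pair: str = "apoe-mapt") -> list[RelationRecord]:
    """A relation table that reconstructs the printed APOE–MAPT paths:
    running the context model at threshold 1 over it reproduces the 19
    published paths exactly."""
    if pair != "apoe-mapt":
        raise KeyError(f"no bundled relation table for {pair!r}")
    return read_relation_table(data_path("relations_apoe_mapt.tsv"))


def load_verified_b_entities(pair: str, model: str) -> tuple[list[str], GoldLabels]:
    """Expert-verified B entities for a discovery case.

    Returns the extracted B symbols in published order and gold labels whose
    relevant set holds the symbols judged relevant (marked O).
    """
    try:
        name = VERIFICATION_FILES[(pair, model)]
    except KeyError:
        raise KeyError(f"no verification table for pair={pair!r}, model={model!r}") from None
    return read_verification_table(data_path(name))
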