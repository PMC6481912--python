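import pytest

from ctxabc.datasets import (
    load_demo_abstract,
    load_demo_relations,
    load_reference_vocabularies,
)
from ctxabc.hierarchy import HierarchyVocabulary


@pytest.fixture(scope="session")
def reference_vocabs():
    return load_reference_vocabularies()


@pytest.fixture()
def demo_abstract():
    return load_demo_abstract()


@pytest.fixture()
def demo_relations():
    return load_demo_relations()


@pytest.fixture(scope="session")
def dementia_vocab():
    """Dementia sub-tree: alzheimer and huntington disease are siblings."""
    vocab = HierarchyVocabulary(element_type="disease")
    vocab.add("dementia", "C10.228.140.380")
    vocab.add("alzheimer disease", "C10.228.140.380.100")
    vocab.add("huntington disease", "C10.228.140.380.300")
    vocab.add("parkinson disease", "C10.228.662.600.400")
    vocab.add("tuberculosis", "C01.800.200")
    return vocab
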