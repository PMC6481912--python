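import math

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctxabc.hierarchy import (
    DEFAULT_MAX_DISTANCES,
    UNRELATED,
    HierarchyVocabulary,
    UnknownTermError,
    context_similarity,
    element_similarity,
    load_hierarchy,
    tree_distance,
    write_hierarchy,
)
from ctxabc.relations import CONTEXT_SLOTS, ContextTuple
from ctxabc.simulate import generate_hierarchy


def bfs_distance(vocab, term1, term2):
    """Independent oracle: shortest path on the explicit prefix tree."""
    graph = nx.Graph()
    for positions in vocab.positions.values():
        for position in positions:
            for k in range(1, len(position)):
                graph.add_edge(position[:k], position[: k + 1])
            graph.add_node(position)
    best = UNRELATED
    for p1 in vocab.lookup(term1):
        for p2 in vocab.lookup(term2):
            try:
                d = nx.shortest_path_length(graph, p1, p2)
            except nx.NetworkXNoPath:
                continue
            if best is UNRELATED or d < best:
                best = d
    return best


class TestLoadHierarchy:
    def test_dementia_siblings(self, tmp_path):
        path = tmp_path / "disease.tsv"
        path.write_text("dementia\tC10.228.140.380\n"
                        "alzheimer disease\tC10.228.140.380.100\n"
                        "huntington disease\tC10.228.140.380.300\n")
        vocab = load_hierarchy(path, "disease")
        assert len(vocab) == 3
        assert tree_distance("alzheimer disease", "dementia", vocab) == 1
        assert tree_distance("alzheimer disease", "huntington disease", vocab) == 2

    def test_empty_file_gives_empty_vocab(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        vocab = load_hierarchy(path, "cell")
        assert len(vocab) == 0
        with pytest.raises(UnknownTermError):
            vocab.lookup("anything")

    def test_malformed_position_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("ok\tC10.1\nbad\tC10..5\n")
        with pytest.raises(ValueError, match=":2"):
            load_hierarchy(path, "disease")

    def test_max_distance_defaults(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("x\tC01\n")
        for element_type, expected in DEFAULT_MAX_DISTANCES.items():
            assert load_hierarchy(path, element_type).max_distance == expected
        assert load_hierarchy(path, "disease", max_distance=5).max_distance == 5

    @pytest.mark.parametrize("seed", [0, 1])
    def test_round_trip_generated_hierarchy(self, tmp_path, seed):
        vocab = generate_hierarchy("drug", branching=3, depth=3, n_terms=15, seed=seed)
        path = tmp_path / "h.tsv"
        write_hierarchy(vocab, path)
        assert load_hierarchy(path, "drug").positions == vocab.positions


class TestTreeDistance:
    def test_identical_term_distance_zero(self, dementia_vocab):
        assert tree_distance("dementia", "dementia", dementia_vocab) == 0

    def test_cross_category_unrelated(self, dementia_vocab):
        assert tree_distance("dementia", "tuberculosis", dementia_vocab) is UNRELATED

    def test_unknown_term_named(self, dementia_vocab):
        with pytest.raises(UnknownTermError, match="nosuchterm"):
            tree_distance("nosuchterm", "dementia", dementia_vocab)

    def test_normalization_on_lookup(self, dementia_vocab):
        assert tree_distance("Alzheimer Disease", "alzheimerdisease", dementia_vocab) == 0

    def test_poly_hierarchy_takes_minimum(self):
        vocab = HierarchyVocabulary(element_type="disease")
        vocab.add("a", "C01.1.1.1.1")
        vocab.add("a", "C02.5")
        vocab.add("b", "C02.5.1")
        assert tree_distance("a", "b", vocab) == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bfs_oracle_on_random_hierarchies(self, seed):
        vocab = generate_hierarchy("disease", branching=3, depth=4, n_terms=25,
                                   seed=seed, n_roots=2)
        terms = vocab.terms
        for t1 in terms:
            for t2 in terms:
                assert tree_distance(t1, t2, vocab) == bfs_distance(vocab, t1, t2)


class TestElementSimilarity:
    def test_identical_terms_score_one(self, dementia_vocab):
        assert element_similarity("dementia", "dementia", dementia_vocab) == 1.0

    def test_siblings_under_dementia(self, dementia_vocab):
        expected = 1 - 2 / 26  # oracle distance 2, published disease maximum 26
        score = element_similarity("alzheimer disease", "huntington disease", dementia_vocab)
        assert score == pytest.approx(expected)

    def test_unrelated_categories_score_zero(self, dementia_vocab):
        assert element_similarity("dementia", "tuberculosis", dementia_vocab) == 0.0

    def test_distance_beyond_maximum_clamps_to_zero(self):
        vocab = HierarchyVocabulary(element_type="organism", max_distance=3)
        vocab.add("deep1", "K01.1.1.1.1.1")
        vocab.add("deep2", "K01.2.2.2.2.2")
        assert element_similarity("deep1", "deep2", vocab) == 0.0

    def test_set_valued_maximum_over_cross_pairs(self, dementia_vocab):
        score = element_similarity({"tuberculosis", "dementia"},
                                   {"alzheimer disease"}, dementia_vocab)
        assert score == pytest.approx(1 - 1 / 26)


class TestContextSimilarity:
    def vocabs(self, dementia_vocab):
        return {slot: dementia_vocab if slot == "disease"
                else HierarchyVocabulary(element_type=slot) for slot in CONTEXT_SLOTS}

    def test_identical_single_disease_scores_one(self, dementia_vocab):
        ctx = ContextTuple.from_terms(disease="alzheimerdisease")
        assert context_similarity(ctx, ctx, self.vocabs(dementia_vocab)) == 1.0

    def test_unrelated_contexts_score_zero(self, dementia_vocab):
        a = ContextTuple.from_terms(disease="alzheimerdisease")
        b = ContextTuple.from_terms(disease="tuberculosis")
        assert context_similarity(a, b, self.vocabs(dementia_vocab)) == 0.0

    def test_extra_slot_dilutes_by_sqrt(self, dementia_vocab):
        vocabs = self.vocabs(dementia_vocab)
        vocabs["organism"].add("mouse", "K01.1")
        a = ContextTuple.from_terms(disease="dementia")
        b = ContextTuple.from_terms(disease="dementia", organism="mouse")
        assert context_similarity(a, b, vocabs) == pytest.approx(1 / math.sqrt(2))

    def test_empty_context_scores_zero(self, dementia_vocab):
        ctx = ContextTuple.from_terms(disease="dementia")
        assert context_similarity(ctx, ContextTuple(), self.vocabs(dementia_vocab)) == 0.0
        assert context_similarity(ContextTuple(), ContextTuple(),
                                  self.vocabs(dementia_vocab)) == 0.0

    def test_shared_counts_variant(self, dementia_vocab):
        vocabs = self.vocabs(dementia_vocab)
        vocabs["organism"].add("mouse", "K01.1")
        a = ContextTuple.from_terms(disease="dementia")
        b = ContextTuple.from_terms(disease="dementia", organism="mouse")
        assert context_similarity(a, b, vocabs, shared_counts=True) == 1.0


# --- property suite against an independent oracle --------------------------

def _toy_vocabs():
    vocabs = {}
    for i, slot in enumerate(CONTEXT_SLOTS):
        vocab = HierarchyVocabulary(element_type=slot)
        root = f"{slot[:1].upper()}{i}"
        vocab.add(f"{slot}_a", f"{root}.1")
        vocab.add(f"{slot}_b", f"{root}.1.1")
        vocab.add(f"{slot}_c", f"{root}.2.1")
        vocab.add(f"{slot}_d", f"{root}x.9")  # unrelated category
        vocab.add(f"{slot}_e", root)
        vocabs[slot] = vocab
    return vocabs


TOY_VOCABS = _toy_vocabs()


def oracle_context_similarity(ctx1, ctx2, vocabs):
    """Brute-force reimplementation via the BFS path oracle."""
    n1 = sum(ctx1.slot(s) is not None for s in CONTEXT_SLOTS)
    n2 = sum(ctx2.slot(s) is not None for s in CONTEXT_SLOTS)
    if n1 == 0 or n2 == 0:
        return 0.0
    total = 0.0
    for slot in CONTEXT_SLOTS:
        v1, v2 = ctx1.slot(slot), ctx2.slot(slot)
        if v1 is None or v2 is None:
            continue
        best = 0.0
        for t1 in v1:
            for t2 in v2:
                d = bfs_distance(vocabs[slot], t1, t2)
                if d is not UNRELATED:
                    best = max(best, max(0.0, 1 - d / vocabs[slot].max_distance))
        total += best
    return total / math.sqrt(n1 * n2)


def toy_tuples(max_terms=2):
    slot_values = {
        slot: st.one_of(
            st.none(),
            st.frozensets(st.sampled_from(sorted(TOY_VOCABS[slot].positions)),
                          min_size=1, max_size=max_terms),
        )
        for slot in CONTEXT_SLOTS
    }
    return st.builds(ContextTuple, **slot_values)


@settings(max_examples=150, deadline=None)
@given(toy_tuples(), toy_tuples())
def test_symmetry_and_bounds(ctx1, ctx2):
    forward = context_similarity(ctx1, ctx2, TOY_VOCABS)
    backward = context_similarity(ctx2, ctx1, TOY_VOCABS)
    assert forward == pytest.approx(backward)
    assert 0.0 <= forward <= 1.0 + 1e-12


@settings(max_examples=150, deadline=None)
@given(toy_tuples(), toy_tuples())
def test_agrees_with_brute_force_oracle(ctx1, ctx2):
    assert context_similarity(ctx1, ctx2, TOY_VOCABS) == pytest.approx(
        oracle_context_similarity(ctx1, ctx2, TOY_VOCABS))


@settings(max_examples=100, deadline=None)
@given(toy_tuples())
def test_score_one_iff_identical_counts_and_perfect_slots(ctx):
    if ctx.element_count:
        assert context_similarity(ctx, ctx, TOY_VOCABS) == pytest.approx(1.0)
    if ctx.element_count and ctx.organism is None:
        # adding a slot to one side breaks the equal-element-count condition
        extended = ctx.merge(ContextTuple.from_terms(organism="organism_e"))
        assert context_similarity(ctx, extended, TOY_VOCABS) < 1.0
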