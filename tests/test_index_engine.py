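"""Analyzer chain, concept-token injection, BM25 ranking, and boolean semantics."""

import math
import random

import pytest

from biodataseek._tokenize import tokenize
from biodataseek.corpus_io import flatten_record
from biodataseek.index_engine import (
    AnalyzerConfig,
    And,
    ConceptQuery,
    Index,
    IndexError_,
    Or,
    Phrase,
    Term,
    analyze,
    build_index,
    execute_query,
    inject_concept_tokens,
)
from biodataseek.ontology_gazetteer import Concept, Ontology, build_gazetteer, tag_entities


# ---------------------------------------------------------------------------
# Analyzer


def test_analyze_basic():
    tokens = analyze("DNA Repair", AnalyzerConfig())
    assert [(t.norm, t.position) for t in tokens] == [("dna", 0), ("repair", 1)]


def test_porter_conflates_plural():
    config = AnalyzerConfig(stemmer="english_porter")
    one = analyze("signaling pathways", config)
    two = analyze("signaling pathway", config)
    assert one[1].norm == two[1].norm


def test_stop_filter_leaves_position_holes():
    config = AnalyzerConfig(stop_filter=True)
    tokens = analyze("dna and repair", config)
    assert [(t.norm, t.position) for t in tokens] == [("dna", 0), ("repair", 2)]


def test_analyze_idempotent_on_norms():
    rng = random.Random(5)
    words = ["Studies", "of", "DNA", "repair", "signaling", "pathways", "tgf-beta"]
    config = AnalyzerConfig(stemmer="english_porter")
    for _ in range(100):
        text = " ".join(rng.choice(words) for _ in range(rng.randint(1, 10)))
        first = [t.norm for t in analyze(text, config)]
        second = [t.norm for t in analyze(" ".join(first), config)]
        assert first == second


# ---------------------------------------------------------------------------
# Concept injection


def test_injection_positions(example_gazetteer, example_ontology):
    text = "breast cancer"
    tokens = analyze(text, AnalyzerConfig())
    mentions = tag_entities(tokenize(text), example_gazetteer)
    injected = inject_concept_tokens(tokens, mentions, example_ontology, True)
    by_kind = {
        t.kind: (t.norm, t.position) for t in injected if t.kind != "word"
    }
    # explicit id at the position of the mention's last word; ancestor implicit
    assert by_kind["concept_explicit"] == ("M0005", 1)
    assert by_kind["concept_implicit"] == ("i#M0007", 1)
    assert [(t.norm, t.position) for t in injected if t.kind == "word"] == [
        ("breast", 0), ("cancer", 1),
    ]


def test_injection_flag_off(example_gazetteer, example_ontology):
    text = "breast cancer"
    tokens = analyze(text, AnalyzerConfig())
    mentions = tag_entities(tokenize(text), example_gazetteer)
    injected = inject_concept_tokens(tokens, mentions, example_ontology, False)
    assert all(t.kind != "concept_implicit" for t in injected)


def test_injection_inverse(example_gazetteer, example_ontology):
    text = "regulation of dna repair"
    tokens = analyze(text, AnalyzerConfig())
    mentions = tag_entities(tokenize(text), example_gazetteer)
    injected = inject_concept_tokens(tokens, mentions, example_ontology, True)
    words_only = [t for t in injected if t.kind == "word"]
    assert words_only == tokens


def test_injection_out_of_range(example_ontology):
    from biodataseek.ontology_gazetteer import EntityMention

    tokens = analyze("one two", AnalyzerConfig())
    bad = EntityMention(5, 7, "x", frozenset({("M0001", "mesh_like")}))
    with pytest.raises(IndexError_):
        inject_concept_tokens(tokens, [bad], example_ontology, True)


# ---------------------------------------------------------------------------
# BM25 oracle


def _bm25_oracle(index, term, doc_id, field=""):
    """Closed-form BM25, recomputed independently from raw postings."""
    postings = index.postings[field].get(term, {})
    df = len(postings)
    tf = len(postings.get(doc_id, []))
    if tf == 0:
        return 0.0
    n = index.n_docs
    idf = math.log(1 + (n - df + 0.5) / (df + 0.5))
    dl = index.doc_len[field][doc_id]
    avgdl = sum(index.doc_len[field].values()) / len(index.doc_len[field])
    return idf * tf * 2.2 / (tf + 1.2 * (1 - 0.75 + 0.75 * dl / avgdl))


def test_single_term_scores_match_bm25_oracle(tiny_index):
    hits = execute_query(Term(text="repair"), tiny_index, top_n=10)
    assert hits
    for hit in hits:
        assert hit.score == pytest.approx(
            _bm25_oracle(tiny_index, "repair", hit.doc_id), abs=1e-9
        )


def test_df_tf_single_doc():
    records = [flatten_record({"f": "hello"}, "d1")]
    index = build_index(records)
    assert len(index.postings[""]["hello"]) == 1
    assert len(index.postings[""]["hello"]["d1"]) == 1


def test_concept_token_frequency_drives_ranking(example_ontology):
    gazetteer = build_gazetteer([Concept("M0005", "Breast Cancer")])
    records = [
        flatten_record({"f": "breast cancer breast cancer breast cancer"}, "many"),
        flatten_record({"f": "breast cancer and unrelated padding words here"}, "one"),
    ]
    index = build_index(records, gazetteer, example_ontology)
    hits = execute_query(ConceptQuery("M0005"), index, top_n=10)
    assert [h.doc_id for h in hits] == ["many", "one"]


def test_index_round_trip(tmp_path, tiny_index):
    tiny_index.save(str(tmp_path / "idx"))
    reloaded = Index.load(str(tmp_path / "idx"))
    probes = [
        Term(text="repair"),
        Phrase(texts=("dna", "repair")),
        ConceptQuery("M0005"),
        Or(children=(Term(text="estrogen"), Term(text="cancer")), min_should_match=1),
    ]
    for probe in probes:
        assert execute_query(probe, tiny_index, 10) == execute_query(probe, reloaded, 10)


# ---------------------------------------------------------------------------
# Boolean / phrase semantics


def test_phrase_slop_semantics(tiny_index):
    exact = execute_query(Phrase(texts=("dna", "repair"), slop=0), tiny_index, 10)
    assert {h.doc_id for h in exact} == {"d1"}
    sloppy = execute_query(Phrase(texts=("dna", "repair"), slop=1), tiny_index, 10)
    assert {h.doc_id for h in sloppy} == {"d1", "d3"}


def test_phrase_cannot_cross_field_gap():
    record = flatten_record({"a": "alpha", "b": "beta"}, "d")
    index = build_index([record], gap_size=10)
    assert not execute_query(Phrase(texts=("alpha", "beta"), slop=9), index, 10)
    assert execute_query(Phrase(texts=("alpha", "beta"), slop=10), index, 10)


def test_or_with_full_msm_equals_and(tiny_index):
    children = (Term(text="breast"), Term(text="cancer"))
    or_docs = {
        h.doc_id
        for h in execute_query(
            Or(children=children, min_should_match=2), tiny_index, 10
        )
    }
    and_docs = {
        h.doc_id for h in execute_query(And(children=children), tiny_index, 10)
    }
    assert or_docs == and_docs


def test_boolean_semantics_match_brute_force_filter(tiny_corpus, tiny_index):
    """AND/OR/msm doc sets equal a direct containment filter on record text."""
    rng = random.Random(11)
    vocabulary = ["dna", "repair", "breast", "cancer", "estrogen", "survey", "study"]
    texts = {
        r.doc_id: {t.lower for t in tokenize(r.all_text)} for r in tiny_corpus
    }
    for _ in range(50):
        terms = rng.sample(vocabulary, rng.randint(2, 4))
        msm = rng.randint(1, len(terms))
        node = Or(
            children=tuple(Term(text=t) for t in terms), min_should_match=msm
        )
        got = {h.doc_id for h in execute_query(node, tiny_index, 10)}
        expected = {
            doc
            for doc, words in texts.items()
            if sum(1 for t in terms if t in words) >= msm
        }
        assert got == expected


def test_boost_linearity(tiny_index):
    node = Or(
        children=(Term(text="dna"), Phrase(texts=("breast", "cancer"))),
        min_should_match=1,
    )
    base = execute_query(node, tiny_index, 10)
    scaled = execute_query(
        Or(children=node.children, min_should_match=1, boost=3.0), tiny_index, 10
    )
    assert [h.doc_id for h in base] == [h.doc_id for h in scaled]
    for b, s in zip(base, scaled):
        assert s.score == pytest.approx(3.0 * b.score, rel=1e-12)


def test_unmatched_or_child_is_inert(tiny_index):
    children = (Term(text="estrogen"), Term(text="cancer"))
    with_ghost = children + (Term(text="zzz-nonexistent"),)
    before = execute_query(Or(children=children, min_should_match=1), tiny_index, 10)
    after = execute_query(Or(children=with_ghost, min_should_match=1), tiny_index, 10)
    assert [(h.doc_id, h.score) for h in before] == [(h.doc_id, h.score) for h in after]


def test_word_phrases_injection_invariant(tiny_corpus, example_gazetteer, example_ontology):
    plain = build_index(tiny_corpus)
    with_concepts = build_index(tiny_corpus, example_gazetteer, example_ontology)
    probe = Phrase(texts=("breast", "cancer"), slop=0)
    assert {h.doc_id for h in execute_query(probe, plain, 10)} == {
        h.doc_id for h in execute_query(probe, with_concepts, 10)
    }


def test_query_errors(tiny_index):
    with pytest.raises(IndexError_):
        execute_query(Term(text="x", field="no.such.field"), tiny_index, 10)
    with pytest.raises(IndexError_):
        execute_query(Term(text="x"), tiny_index, 0)
    with pytest.raises(IndexError_):
        Phrase(texts=("one",))
    with pytest.raises(IndexError_):
        Or(children=(Term(text="x"),), min_should_match=2)


def test_duplicate_doc_id_rejected(tiny_corpus):
    index = build_index(tiny_corpus)
    with pytest.raises(IndexError_, match="duplicate"):
        index.add_record(tiny_corpus[0])
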