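"""Query normalization, parsing, tagging, and the four query builders."""

import random

import pytest

from biodataseek.corpus_io import FieldValueDictionary, flatten_record, build_field_value_dictionary
from biodataseek.embedding_expansion import LexiconExpander
from biodataseek.index_engine import And, ConceptQuery, Or, Phrase, Term, build_index, execute_query
from biodataseek.ontology_gazetteer import Concept, Ontology, Source, build_gazetteer
from biodataseek.query_pipeline import (
    ParseError,
    QueryConfig,
    build_concept_expanded_query,
    build_embedding_expanded_query,
    build_field_tagged_query,
    build_unigram_query,
    load_mapping_file,
    normalize_query,
    parse_query,
    tag_parsed_query,
)

from conftest import WORKED_QUERY


# ---------------------------------------------------------------------------
# Normalization


@pytest.mark.parametrize(
    "text, expected",
    [
        ("M. musculus liver", "Mus musculus liver"),
        ("NF-κB", "NF-kappaB"),
        ("β-catenin in D. melanogaster", "beta-catenin in Drosophila melanogaster"),
        ("plain query", "plain query"),
    ],
)
def test_normalize_query(text, expected):
    assert normalize_query(text) == expected


def test_normalize_with_empty_maps_is_identity():
    assert normalize_query("M. musculus β", {}, {}) == "M. musculus β"


def test_malformed_mapping_file(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text("good\tvalue\nbad-line-no-tab\n")
    with pytest.raises(ParseError, match=":2"):
        load_mapping_file(str(path))


# ---------------------------------------------------------------------------
# Parsing


def test_worked_query_kept_and_ignored():
    parsed = parse_query(WORKED_QUERY)
    assert parsed.kept_tokens == [
        "regulation", "dna", "repair", "estrogen", "signaling", "pathway",
        "breast", "cancer", "patients",
    ]
    assert parsed.ignored_words == ["of", "related", "to", "the", "in"]
    assert parsed.chunks == [(0, 1), (1, 3), (3, 6), (6, 9)]


def test_single_token_query():
    parsed = parse_query("cancer")
    assert parsed.chunks == [(0, 1)] and parsed.ignored_words == []


def test_head_pattern_stripped():
    parsed = parse_query("find data on liver fibrosis")
    assert parsed.kept_tokens == ["liver", "fibrosis"]


def test_empty_query_raises():
    with pytest.raises(ParseError, match="no content"):
        parse_query("of the in")


# ---------------------------------------------------------------------------
# Tagging


def test_worked_query_tagging(example_gazetteer):
    parsed = tag_parsed_query(parse_query(WORKED_QUERY), example_gazetteer)
    assert len(parsed.mesh_mentions) == 5
    assert parsed.gene_mentions == []
    assert parsed.other_terms == ["patients"]


def test_gene_tagging():
    gazetteer = build_gazetteer(
        [Concept("G1", "BRCA1", source=Source.GENE, case_sensitive=False)]
    )
    parsed = tag_parsed_query(parse_query("BRCA1 expression"))
    assert parsed.other_terms  # untagged without gazetteer
    parsed = tag_parsed_query(parse_query("BRCA1 expression"), gazetteer)
    assert len(parsed.gene_mentions) == 1
    assert parsed.gene_mentions[0].ids_for_source(Source.GENE) == ["G1"]


def test_field_value_tagging_precedence(example_gazetteer):
    fv = FieldValueDictionary(
        entries={"breast cancer": {"METADATA.Disease.name": 2}, "patients": {"f.x": 1}}
    )
    parsed = tag_parsed_query(parse_query(WORKED_QUERY), example_gazetteer, fv)
    # gazetteer wins "breast cancer"; fv catches "patients"
    assert len(parsed.mesh_mentions) == 5
    assert parsed.field_tagged == [("patients", "f.x", pytest.approx(0.2))]
    assert parsed.other_terms == []


def test_token_partition_invariant(example_gazetteer):
    """Every kept token lands in exactly one bucket."""
    rng = random.Random(21)
    vocabulary = [
        "regulation", "dna", "repair", "estrogen", "signaling", "pathway",
        "breast", "cancer", "patients", "liver", "of", "the", "in", "fibrosis",
    ]
    fv = FieldValueDictionary(entries={"liver fibrosis": {"f.y": 1}})
    for _ in range(50):
        text = " ".join(rng.choice(vocabulary) for _ in range(rng.randint(1, 12)))
        try:
            parsed = tag_parsed_query(parse_query(text), example_gazetteer, fv)
        except ParseError:
            continue
        counts = [0] * len(parsed.kept_tokens)
        for mention in parsed.mesh_mentions + parsed.gene_mentions:
            for i in range(mention.start, mention.end):
                counts[i] += 1
        for start, end in parsed.field_tagged_spans:
            for i in range(start, end):
                counts[i] += 1
        n_other = len(parsed.other_terms)
        assert counts.count(0) == n_other
        assert all(c <= 1 for c in counts)


# ---------------------------------------------------------------------------
# Builders


def test_unigram_query_shape():
    parsed = parse_query(WORKED_QUERY)
    node = build_unigram_query(parsed)
    assert isinstance(node, Or) and len(node.children) == 9
    assert all(isinstance(c, Term) and c.field == "" for c in node.children)
    single = build_unigram_query(parse_query("cancer"))
    assert isinstance(single, Term)


def test_unigram_node_count_matches_kept_tokens():
    rng = random.Random(3)
    words = ["alpha", "beta", "gamma", "delta", "cancer", "of", "the"]
    for _ in range(30):
        text = " ".join(rng.choice(words) for _ in range(rng.randint(1, 10)))
        try:
            parsed = parse_query(text)
        except ParseError:
            continue
        node = build_unigram_query(parsed)
        n_leaves = len(node.children) if isinstance(node, Or) else 1
        assert n_leaves == len(parsed.kept_tokens)


def test_field_tagged_query_phrase_and_fallback():
    fv = FieldValueDictionary(
        entries={
            "dna repair": {"METADATA.keywords": 3},
            "estrogen": {
                "METADATA.StudyGroup.name": 1,
                "METADATA.Treatment.agent": 2,
            },
        }
    )
    parsed = tag_parsed_query(parse_query(WORKED_QUERY), None, fv)
    node = build_field_tagged_query(parsed)
    phrases = [c for c in node.children if isinstance(c, Phrase)]
    assert phrases == [
        Phrase(texts=("dna", "repair"), field="METADATA.keywords", boost=0.5)
    ]
    multi_field = [c for c in node.children if isinstance(c, Or)]
    assert len(multi_field) == 1 and len(multi_field[0].children) == 2
    assert {c.boost for c in multi_field[0].children} == {0.2, 1.0}


def test_field_tagged_falls_back_to_unigram():
    parsed = tag_parsed_query(parse_query("liver fibrosis"), None, None)
    assert build_field_tagged_query(parsed) == build_unigram_query(parsed)


def test_embedding_expansion_adds_damped_clauses():
    expander = LexiconExpander({"glycolysis": [("gluconeogenesis", 0.9)]})
    parsed = tag_parsed_query(parse_query("glycolysis"), None, None)
    node = build_embedding_expanded_query(parsed, expander)
    assert isinstance(node, Or)
    extra = [c for c in node.children if isinstance(c, Term) and c.text == "gluconeogenesis"]
    assert len(extra) == 1 and extra[0].boost == pytest.approx(0.3)
    # empty expansion -> identical to field-tagged query
    empty = LexiconExpander({})
    assert build_embedding_expanded_query(parsed, empty) == build_field_tagged_query(parsed)


def test_expansion_never_outranks_original_phrase():
    expander = LexiconExpander({"glycolysis": [("gluconeogenesis", 0.9)]})
    records = [
        flatten_record({"f": "glycolysis flux measurements"}, "orig"),
        flatten_record({"f": "gluconeogenesis flux measurements"}, "expanded"),
    ]
    index = build_index(records)
    parsed = tag_parsed_query(parse_query("glycolysis flux"), None, None)
    node = build_embedding_expanded_query(parsed, expander)
    hits = execute_query(node, index, 10)
    assert [h.doc_id for h in hits] == ["orig", "expanded"]


def _sub_query_by_phrase(part1, phrase_text):
    for sub in part1.children:
        for clause in sub.children:
            if isinstance(clause, Phrase) and " ".join(clause.texts) == phrase_text:
                return sub
            if isinstance(clause, Term) and clause.text == phrase_text and clause.boost == 20.0:
                return sub
    raise AssertionError(f"no sub-query for {phrase_text!r}")


def test_concept_expanded_worked_example(example_gazetteer, example_ontology):
    parsed = tag_parsed_query(parse_query(WORKED_QUERY), example_gazetteer)
    node = build_concept_expanded_query(parsed, example_ontology)
    assert isinstance(node, And) and len(node.children) == 2
    part1, part2 = node.children
    assert isinstance(part1, Or) and len(part1.children) == 5
    assert part1.min_should_match == 5  # default "all"

    dna = _sub_query_by_phrase(part1, "dna repair")
    kinds = {}
    for clause in dna.children:
        kinds[type(clause).__name__ + getattr(clause, "concept_id", "")] = clause
    and_clause = next(c for c in dna.children if isinstance(c, And))
    assert and_clause.boost == pytest.approx(0.5)
    assert [t.text for t in and_clause.children] == ["dna", "repair"]
    phrase_clause = next(c for c in dna.children if isinstance(c, Phrase))
    assert phrase_clause.boost == pytest.approx(20.0)
    explicit = [c for c in dna.children if isinstance(c, ConceptQuery) and not c.implicit]
    implicit = [c for c in dna.children if isinstance(c, ConceptQuery) and c.implicit]
    assert any(c.boost == pytest.approx(1.0) for c in explicit)
    assert implicit and implicit[0].boost == pytest.approx(0.5)

    # single-word concept takes the phrase boost
    regulation = _sub_query_by_phrase(part1, "regulation")
    term_clause = next(c for c in regulation.children if isinstance(c, Term))
    assert term_clause.boost == pytest.approx(20.0)

    # other terms: patients^2
    assert part2 == Or(
        children=(Term(text="patients", boost=2.0),), min_should_match=1
    )


def test_concept_query_run5_configuration(example_gazetteer, example_ontology):
    """No descendants and unit boosts anywhere in the tree."""
    config = QueryConfig(include_descendants=False).with_boosts(
        phrase=1.0, and_words=1.0, explicit_id=1.0, implicit_id=1.0,
        descendant_id=1.0, descendant_implicit_id=1.0, other_term=1.0,
    )
    parsed = tag_parsed_query(parse_query(WORKED_QUERY), example_gazetteer)
    node = build_concept_expanded_query(parsed, example_ontology, config)

    described = []

    def walk(n):
        described.append(n)
        for child in getattr(n, "children", ()):  # leaves have no children
            walk(child)

    walk(node)
    concept_ids = {n.concept_id for n in described if isinstance(n, ConceptQuery)}
    # descendants of M0006/M0007 (M0002, M0005 are mentioned, fine) but no
    # *descendant-only* ids like expanding M0007 -> M0005 duplicates
    for n in described:
        assert getattr(n, "boost", 1.0) == pytest.approx(1.0)
    # the only concept ids present are those explicitly mentioned
    assert concept_ids == {"M0001", "M0002", "M0003", "M0004", "M0005"}


def test_concept_query_with_msm_all_requires_every_subquery(
    example_gazetteer, example_ontology
):
    records = [
        flatten_record({"f": "dna repair estrogen signaling pathway regulation "
                             "breast cancer patients"}, "all"),
        flatten_record({"f": "dna repair patients"}, "some"),
    ]
    index = build_index(records, example_gazetteer, example_ontology)
    parsed = tag_parsed_query(parse_query(WORKED_QUERY), example_gazetteer)
    strict = build_concept_expanded_query(parsed, example_ontology)
    assert {h.doc_id for h in execute_query(strict, index, 10)} == {"all"}
    relaxed = build_concept_expanded_query(
        parsed, example_ontology, QueryConfig(msm_concept_part=1)
    )
    assert {h.doc_id for h in execute_query(relaxed, index, 10)} == {"all", "some"}


def test_builders_are_pure(example_gazetteer, example_ontology):
    parsed = tag_parsed_query(parse_query(WORKED_QUERY), example_gazetteer)
    config = QueryConfig()
    first = build_concept_expanded_query(parsed, example_ontology, config)
    second = build_concept_expanded_query(parsed, example_ontology, config)
    assert first == second


def test_every_kept_token_reaches_a_leaf(example_gazetteer, example_ontology):
    fv = FieldValueDictionary(entries={"liver fibrosis": {"f.y": 1}})
    for text in [WORKED_QUERY, "liver fibrosis in breast cancer", "cancer patients"]:
        parsed = tag_parsed_query(parse_query(text), example_gazetteer, fv)
        for builder in (
            build_unigram_query,
            build_field_tagged_query,
            lambda p: build_concept_expanded_query(p, example_ontology),
        ):
            node = builder(parsed)
            leaf_words = set()

            def walk(n):
                if isinstance(n, Term):
                    leaf_words.add(n.text)
                elif isinstance(n, Phrase):
                    leaf_words.update(n.texts)
                for child in getattr(n, "children", ()):
                    walk(child)

            walk(node)
            for token in parsed.kept_tokens:
                assert token in leaf_words


def test_empty_concept_query_errors(example_ontology):
    parsed = tag_parsed_query(parse_query("breast cancer"), None, None)
    parsed.other_terms = []  # force both parts empty
    with pytest.raises(ParseError, match="empty query"):
        build_concept_expanded_query(parsed, example_ontology)
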