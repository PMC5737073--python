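import pytest

from biodataseek.corpus_io import flatten_record
from biodataseek.index_engine import AnalyzerConfig, build_index
from biodataseek.ontology_gazetteer import Concept, Ontology, build_gazetteer
from biodataseek.synthetic_fixtures import worked_example_concepts

WORKED_QUERY = (
    "Regulation of DNA repair related to the estrogen signaling pathway "
    "in breast cancer patients"
)


@pytest.fixture(scope="session")
def example_concepts():
    return worked_example_concepts(n_distractors=10, seed=0)


@pytest.fixture(scope="session")
def example_gazetteer(example_concepts):
    return build_gazetteer(example_concepts)


@pytest.fixture(scope="session")
def example_ontology(example_concepts):
    return Ontology(example_concepts)


@pytest.fixture()
def tiny_corpus():
    raws = [
        {"_id": "d1", "METADATA": {"description": "dna repair in breast cancer",
                                   "keywords": ["dna repair"]}},
        {"_id": "d2", "METADATA": {"description": "estrogen signaling pathway study"}},
        {"_id": "d3", "METADATA": {"description": "dna strand repair mechanisms"}},
        {"_id": "d4", "METADATA": {"description": "breast cancer patients cohort"}},
        {"_id": "d5", "METADATA": {"description": "unrelated proteomics survey"}},
    ]
    return [flatten_record(r, r["_id"]) for r in raws]


@pytest.fixture()
def tiny_index(tiny_corpus, example_gazetteer, example_ontology):
    return build_index(
        tiny_corpus,
        example_gazetteer,
        example_ontology,
        analyzer=AnalyzerConfig(),
    )
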