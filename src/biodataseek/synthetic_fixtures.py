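"""Deterministic synthetic fixtures: ontology, genes, corpus, queries, qrels.

Everything every other module needs to be exercised end-to-end is generated
from a single :class:`FixtureSpec` seed — no external downloads. The
generators emulate the shape of the real task: a small concept hierarchy
with synonyms (a fraction written in comma-inverted "B, A" form), a gene
dictionary with case-sensitive symbols, nested metadata records whose text
and entity-bearing structured fields embed known concept surfaces, queries
that name concepts by preferred term, by synonym, or only via a descendant,
and graded judgments that are a known function of concept overlap: grade 2
when a record covers every queried concept (directly or through a
descendant), grade 1 for a strict non-empty subset, 0 otherwise.

Record text is template-based English ("Study of <concept> in <organism>"),
not natural prose — sufficient for exact-match tagging and BM25 but
deliberately simpler than real metadata.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from .ontology_gazetteer import Concept, Ontology, Source

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_ontology",
    "generate_corpus",
    "generate_queries_and_qrels",
    "generate_fixture",
    "worked_example_concepts",
]

_SYLLABLES = [
    "ba", "co", "di", "fe", "gi", "ho", "ju", "ka", "lo", "mu", "ne", "po",
    "qui", "ra", "su", "ta", "vo", "wi", "xa", "zo", "bre", "cli", "dro",
    "fla", "gru", "ple", "sta", "tri",
]

_ORGANISMS = ["human", "mouse", "rat", "zebrafish", "yeast", "fly"]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_concepts: int = 60
    tree_depth: int = 4
    synonyms_per_concept: int = 2
    comma_fraction: float = 0.2
    n_genes: int = 20
    case_sensitive_fraction: float = 0.3
    n_records: int = 300
    fields_per_record: int = 4
    mentions_per_record: int = 3
    n_queries: int = 15
    synonym_query_fraction: float = 0.5
    descendant_query_fraction: float = 0.3
    strata_rate: float | None = None  # e.g. 0.5 to emit a sampled qrels


@dataclass
class GroundTruth:
    """Planted structure the oracle tests check against."""

    # (doc_id, concept_id, surface, field_path)
    mentions: list[tuple[str, str, str, str]] = field(default_factory=list)
    # query_id -> list of (concept_id, surface_used, via) with via in
    # {"preferred", "synonym", "descendant"}
    query_concepts: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    # doc_id -> set of directly planted concept ids
    doc_concepts: dict[str, set[str]] = field(default_factory=dict)


def _word_pool(rng: random.Random, n: int, lengths: tuple[int, int] = (2, 3)) -> list[str]:
    pool: set[str] = set()
    while len(pool) < n:
        word = "".join(
            rng.choice(_SYLLABLES) for _ in range(rng.randint(*lengths))
        )
        pool.add(word)
    return sorted(pool)


def generate_ontology(spec: FixtureSpec) -> tuple[list[Concept], list[Concept]]:
    """Random concept tree plus a flat gene dictionary; pure function of spec."""
    rng = random.Random(spec.seed)
    n_words = spec.n_concepts * (2 + 2 * spec.synonyms_per_concept) + 4 * spec.n_genes
    words = _word_pool(rng, n_words)
    rng.shuffle(words)
    it = iter(words)

    concepts: list[Concept] = []
    depth_of: dict[str, int] = {}
    for i in range(spec.n_concepts):
        cid = f"C{i:04d}"
        preferred = f"{next(it)} {next(it)}" if rng.random() < 0.6 else next(it)
        synonyms = []
        for _ in range(spec.synonyms_per_concept):
            if rng.random() < spec.comma_fraction:
                synonyms.append(f"{next(it).capitalize()}, {next(it).capitalize()}")
            else:
                synonyms.append(f"{next(it)} {next(it)}")
        parents: list[str] = []
        if i > 0:
            candidates = [
                c.concept_id
                for c in concepts
                if depth_of[c.concept_id] < spec.tree_depth - 1
            ]
            if candidates and rng.random() < 0.9:
                parents = [rng.choice(candidates)]
        depth_of[cid] = depth_of[parents[0]] + 1 if parents else 0
        concepts.append(
            Concept(
                concept_id=cid,
                preferred_term=preferred,
                synonyms=synonyms,
                parent_ids=parents,
                source=Source.MESH_LIKE,
            )
        )

    genes: list[Concept] = []
    for i in range(spec.n_genes):
        gid = f"G{i:04d}"
        stem = next(it)
        symbol = stem[:4].capitalize() + str(rng.randint(1, 9))
        genes.append(
            Concept(
                concept_id=gid,
                preferred_term=symbol,
                synonyms=[f"{stem} gene"],
                source=Source.GENE,
                case_sensitive=rng.random() < spec.case_sensitive_fraction,
            )
        )
    return concepts, genes


def generate_corpus(
    spec: FixtureSpec, concepts: list[Concept], genes: list[Concept] | None = None
) -> tuple[list[dict], GroundTruth]:
    """Records embedding known concept surfaces in text and structured fields."""
    rng = random.Random(spec.seed + 1)
    truth = GroundTruth()
    records: list[dict] = []
    genes = genes or []
    for i in range(spec.n_records):
        doc_id = f"R{i:05d}"
        n_mentions = spec.mentions_per_record
        chosen = rng.sample(concepts, min(n_mentions, len(concepts))) if concepts else []
        organism = rng.choice(_ORGANISMS)
        surfaces = [c.preferred_term for c in chosen]
        sentences = [
            f"Study of {surfaces[0]} in {organism} samples." if surfaces else
            f"Observational {organism} cohort."
        ]
        for surface in surfaces[1:]:
            sentences.append(f"Measurements relating to {surface} were collected.")
        record: dict = {
            "_id": doc_id,
            "TITLE": f"Dataset {i}: {surfaces[0] if surfaces else organism} profiling",
            "METADATA": {
                "description": " ".join(sentences),
                "organism": organism,
            },
        }
        if chosen:
            record["METADATA"]["Disease"] = {"name": chosen[0].preferred_term}
            record["METADATA"]["keywords"] = [c.preferred_term for c in chosen[:2]]
        if genes and rng.random() < 0.3:
            gene = rng.choice(genes)
            record["METADATA"]["Gene"] = {"symbol": gene.preferred_term}
            truth.mentions.append(
                (doc_id, gene.concept_id, gene.preferred_term, "METADATA.Gene.symbol")
            )
        for concept in chosen:
            truth.mentions.append(
                (doc_id, concept.concept_id, concept.preferred_term, "METADATA.description")
            )
        truth.doc_concepts[doc_id] = {c.concept_id for c in chosen}
        records.append(record)
    return records, truth


def generate_queries_and_qrels(
    spec: FixtureSpec,
    concepts: list[Concept],
    truth: GroundTruth,
) -> tuple[list[tuple[str, str]], dict[tuple[str, str], int]]:
    """Queries naming 1-3 concepts and grades from planted-concept overlap.

    A query names each target concept by a synonym with probability
    ``synonym_query_fraction``; with probability ``descendant_query_fraction``
    a target is replaced by a *parent* of a planted concept, so only
    descendant expansion can reach the relevant records. Grade 2 = record
    covers all targets (directly or via a descendant), 1 = strict subset,
    0 otherwise.
    """
    rng = random.Random(spec.seed + 2)
    ontology = Ontology(list(concepts))
    by_id = {c.concept_id: c for c in concepts}
    planted_ids = sorted({cid for _d, cid, _s, _f in truth.mentions if cid in by_id})

    queries: list[tuple[str, str]] = []
    qrels: dict[tuple[str, str], int] = {}
    # surrounding words are all stop/interstitial so only concept surfaces
    # survive parsing
    templates = [
        "find data on {}",
        "datasets on {} studies",
        "search for {}",
        "{} related datasets",
    ]
    for qi in range(spec.n_queries):
        qid = f"Q{qi + 1:03d}"
        n_targets = rng.randint(1, 3)
        targets: list[tuple[str, str, str]] = []
        used: set[str] = set()
        for _ in range(n_targets):
            planted = rng.choice(planted_ids)
            if planted in used:
                continue
            used.add(planted)
            concept = by_id[planted]
            if rng.random() < spec.descendant_query_fraction and concept.parent_ids:
                parent = by_id[concept.parent_ids[0]]
                targets.append((parent.concept_id, parent.preferred_term, "descendant"))
            elif rng.random() < spec.synonym_query_fraction and concept.synonyms:
                synonym = rng.choice(concept.synonyms)
                if "," in synonym:
                    left, right = (p.strip() for p in synonym.split(","))
                    synonym = f"{right} {left}"
                targets.append((concept.concept_id, synonym, "synonym"))
            else:
                targets.append((concept.concept_id, concept.preferred_term, "preferred"))
        if not targets:
            continue
        phrase = " and ".join(surface for _cid, surface, _via in targets)
        queries.append((qid, rng.choice(templates).format(phrase)))
        truth.query_concepts[qid] = targets

        closures = [
            {cid} | set(ontology.descendants(cid)) for cid, _s, _v in targets
        ]
        for doc_id, planted_set in truth.doc_concepts.items():
            covered = sum(1 for closure in closures if planted_set & closure)
            if covered == len(closures):
                qrels[(qid, doc_id)] = 2
            elif covered > 0:
                qrels[(qid, doc_id)] = 1
            else:
                qrels[(qid, doc_id)] = 0
    return queries, qrels


def generate_fixture(spec: FixtureSpec):
    """Convenience wrapper returning (concepts, genes, records, truth, queries, qrels)."""
    concepts, genes = generate_ontology(spec)
    records, truth = generate_corpus(spec, concepts, genes)
    queries, qrels = generate_queries_and_qrels(spec, concepts, truth)
    return concepts, genes, records, truth, queries, qrels


def write_fixture_files(spec: FixtureSpec, directory: str) -> None:
    import os

    from .evaluation import Qrels, write_judgments
    from .ontology_gazetteer import write_concepts_jsonl

    os.makedirs(directory, exist_ok=True)
    concepts, genes, records, truth, queries, qrels = generate_fixture(spec)
    write_concepts_jsonl(concepts, os.path.join(directory, "ontology.jsonl"))
    write_concepts_jsonl(genes, os.path.join(directory, "genes.jsonl"))
    with open(os.path.join(directory, "corpus.jsonl"), "w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps(record, sort_keys=True) + "\n")
    with open(os.path.join(directory, "queries.tsv"), "w", encoding="utf-8") as fh:
        for qid, text in queries:
            fh.write(f"{qid}\t{text}\n")
    qrels_obj = Qrels(grades=dict(qrels))
    if spec.strata_rate is not None:
        rng = random.Random(spec.seed + 3)
        sampled = {
            key: grade for key, grade in qrels.items() if rng.random() < spec.strata_rate
        }
        qrels_obj = Qrels(
            grades=sampled,
            strata={key: ("s1", spec.strata_rate) for key in sampled},
        )
    write_judgments(qrels_obj, os.path.join(directory, "qrels.txt"))
    with open(os.path.join(directory, "mentions.tsv"), "w", encoding="utf-8") as fh:
        for doc_id, cid, surface, path in truth.mentions:
            fh.write(f"{doc_id}\t{cid}\t{surface}\t{path}\n")


# ---------------------------------------------------------------------------
# The worked-example gazetteer used in documentation and smoke checks


def worked_example_concepts(n_distractors: int = 10, seed: int = 0) -> list[Concept]:
    """Five relevant MeSH-like headings plus unrelated distractor headings.

    The five headings cover the canonical example query about DNA-repair
    regulation in the estrogen signalling pathway for breast-cancer patients;
    the hierarchy gives "breast cancer" a parent ("neoplasms") so implicit
    and descendant expansion have something to do.
    """
    rng = random.Random(seed)
    base = [
        Concept("M0001", "Regulation"),
        Concept("M0002", "DNA Repair", synonyms=["Repair, DNA"], parent_ids=["M0006"]),
        Concept("M0003", "Estrogen", synonyms=["Estrogens"]),
        Concept("M0004", "Signaling Pathway", synonyms=["Signal Transduction"]),
        Concept("M0005", "Breast Cancer", synonyms=["Breast Neoplasms"], parent_ids=["M0007"]),
        Concept("M0006", "DNA Metabolism"),
        Concept("M0007", "Neoplasms"),
    ]
    words = _word_pool(rng, 2 * n_distractors)
    for i in range(n_distractors):
        base.append(
            Concept(f"M9{i:03d}", f"{words[2 * i]} {words[2 * i + 1]}")
        )
    return base
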