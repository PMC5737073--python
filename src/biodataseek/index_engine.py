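"""Positional inverted index with concept-token injection and a boolean query AST.

The index stores, per field and for the aggregated text field (named ``""``),
positional postings for word tokens and for concept-identifier tokens injected
at the position of the word that evoked them. Co-positioned concept tokens
participate in tf-idf scoring and are transparent to word-phrase matching.

Ranking is BM25 (k1=1.2, b=0.75) at the term level; phrases score as the sum
of their member terms' BM25 once a positional match within the slop exists;
boolean AND/OR nodes combine child scores with boosts and minimum-should-match
constraints. Implicit (ancestor) concept tokens live in a vocabulary disjoint
from explicit ones via an ``i#`` prefix.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

from ._porter import porter_stem
from ._tokenize import Token, tokenize
from .corpus_io import DEFAULT_GAP_SIZE, MetadataRecord, build_aggregated_text
from .ontology_gazetteer import EntityMention, Gazetteer, Ontology, Source, tag_entities

__all__ = [
    "AnalyzerConfig",
    "AnalyzedToken",
    "Term",
    "Phrase",
    "ConceptQuery",
    "And",
    "Or",
    "ScoredHit",
    "Index",
    "IndexError_",
    "analyze",
    "inject_concept_tokens",
    "build_index",
    "execute_query",
    "implicit_token",
]

BM25_K1 = 1.2
BM25_B = 0.75

AGGREGATED_FIELD = ""

# A small built-in stop list for the index analyzer (the query pipeline ships
# its own, larger customized list).
INDEX_STOPWORDS = frozenset(
    "a an and are as at be but by for if in into is it no not of on or such "
    "that the their then there these they this to was will with".split()
)


class IndexError_(ValueError):
    """Raised for schema violations (unknown field, bad top_n, duplicate doc)."""


@dataclass(frozen=True)
class AnalyzerConfig:
    """Analyzer chain: lowercasing, optional stop filter, optional stemmer.

    Stopped words still consume a token position (a positional hole) so that
    phrase slop semantics are unaffected by the stop filter.
    """

    lowercase: bool = True
    stop_filter: bool = False
    stemmer: str = "none"  # {"none", "english_porter"}
    stopwords: frozenset[str] = INDEX_STOPWORDS

    def norm(self, surface: str) -> str:
        text = surface.lower() if self.lowercase else surface
        if self.stemmer == "english_porter":
            text = porter_stem(text)
        return text


@dataclass(frozen=True)
class AnalyzedToken:
    surface: str
    norm: str
    position: int
    char_start: int = -1
    char_end: int = -1
    kind: str = "word"  # {"word", "concept_explicit", "concept_implicit"}


def analyze(text: str, config: AnalyzerConfig, position_offset: int = 0) -> list[AnalyzedToken]:
    """Tokenize and normalize *text*; stopped tokens leave positional holes."""
    out: list[AnalyzedToken] = []
    for position, token in enumerate(tokenize(text)):
        if config.stop_filter and token.lower in config.stopwords:
            continue
        out.append(
            AnalyzedToken(
                surface=token.surface,
                norm=config.norm(token.surface),
                position=position_offset + position,
                char_start=token.char_start,
                char_end=token.char_end,
            )
        )
    return out


def implicit_token(concept_id: str) -> str:
    """Implicit (ancestor) concepts occupy a disjoint vocabulary."""
    return f"i#{concept_id}"


def inject_concept_tokens(
    tokens: list[AnalyzedToken],
    mentions: list[EntityMention],
    ontology: Ontology | None,
    include_ancestors: bool = True,
    position_offset: int = 0,
) -> list[AnalyzedToken]:
    """Insert concept-id tokens co-positioned with each mention's last word.

    Mentions index the *raw* token stream the analyzer saw; because stopped
    words keep their positions, mention token indices equal analyzer positions
    (plus any offset). Each explicit concept id becomes one token; ancestors
    (mesh_like only) become implicit tokens at the same position.
    """
    if not mentions:
        return list(tokens)
    max_position = max((t.position for t in tokens), default=-1)
    out = list(tokens)
    for mention in mentions:
        position = position_offset + mention.end - 1
        if position > max_position:
            raise IndexError_(
                f"mention span {mention.start}:{mention.end} outside token stream"
            )
        for concept_id, source in sorted(mention.concept_ids):
            out.append(
                AnalyzedToken(
                    surface=concept_id,
                    norm=concept_id,
                    position=position,
                    kind="concept_explicit",
                )
            )
            if (
                include_ancestors
                and ontology is not None
                and source == Source.MESH_LIKE.value
                and concept_id in ontology
            ):
                for ancestor in ontology.ancestors(concept_id):
                    out.append(
                        AnalyzedToken(
                            surface=ancestor,
                            norm=implicit_token(ancestor),
                            position=position,
                            kind="concept_implicit",
                        )
                    )
    out.sort(key=lambda t: (t.position, t.kind != "word", t.norm))
    return out


# ---------------------------------------------------------------------------
# Query AST


@dataclass(frozen=True)
class Term:
    text: str
    field: str = AGGREGATED_FIELD
    boost: float = 1.0


@dataclass(frozen=True)
class Phrase:
    texts: tuple[str, ...]
    field: str = AGGREGATED_FIELD
    slop: int = 0
    boost: float = 1.0

    def __post_init__(self) -> None:
        if len(self.texts) < 2:
            raise IndexError_("PHRASE requires at least 2 texts")


@dataclass(frozen=True)
class ConceptQuery:
    concept_id: str
    implicit: bool = False
    boost: float = 1.0
    field: str = AGGREGATED_FIELD


@dataclass(frozen=True)
class And:
    children: tuple
    boost: float = 1.0


@dataclass(frozen=True)
class Or:
    children: tuple
    min_should_match: int = 1
    boost: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.min_should_match <= len(self.children):
            raise IndexError_(
                f"min_should_match {self.min_should_match} outside "
                f"[1, {len(self.children)}]"
            )


QueryNode = Term | Phrase | ConceptQuery | And | Or


def scale_boost(node: QueryNode, factor: float) -> QueryNode:
    return replace(node, boost=node.boost * factor)


@dataclass(frozen=True)
class ScoredHit:
    doc_id: str
    score: float
    matched_clause_count: int = 1


# ---------------------------------------------------------------------------
# Index


class Index:
    """Positional inverted index over a metadata corpus.

    Postings layout: ``postings[field][term][doc_id] -> [positions]``. Word
    tokens and concept tokens share each field's posting space; document
    length counts word tokens only.
    """

    def __init__(self, analyzer: AnalyzerConfig | None = None, gap_size: int = DEFAULT_GAP_SIZE):
        self.analyzer = analyzer or AnalyzerConfig()
        self.gap_size = gap_size
        self.postings: dict[str, dict[str, dict[str, list[int]]]] = {AGGREGATED_FIELD: {}}
        self.doc_len: dict[str, dict[str, int]] = {AGGREGATED_FIELD: {}}
        self.doc_ids: list[str] = []

    # -- construction

    def add_record(
        self,
        record: MetadataRecord,
        gazetteer: Gazetteer | None = None,
        ontology: Ontology | None = None,
        include_ancestors: bool = True,
    ) -> None:
        if record.doc_id in set(self.doc_ids):
            raise IndexError_(f"duplicate doc_id {record.doc_id!r}")
        self.doc_ids.append(record.doc_id)
        aggregated = build_aggregated_text(record, gap_size=self.gap_size)
        field_streams: dict[str, list[AnalyzedToken]] = {AGGREGATED_FIELD: []}
        field_positions: dict[str, int] = {}
        for path, value, _char, agg_position in aggregated.segments:
            raw_tokens = tokenize(value)
            mentions = (
                tag_entities(raw_tokens, gazetteer) if gazetteer is not None else []
            )
            analyzed = analyze(value, self.analyzer)
            # aggregated field: offset by the segment's global position
            agg_tokens = [
                replace(t, position=t.position + agg_position) for t in analyzed
            ]
            agg_tokens = inject_concept_tokens(
                agg_tokens, mentions, ontology, include_ancestors, position_offset=agg_position
            )
            field_streams[AGGREGATED_FIELD].extend(agg_tokens)
            # per-field stream: values of one field separated by the same gap
            base = field_positions.get(path, 0)
            fld_tokens = [replace(t, position=t.position + base) for t in analyzed]
            fld_tokens = inject_concept_tokens(
                fld_tokens, mentions, ontology, include_ancestors, position_offset=base
            )
            field_streams.setdefault(path, []).extend(fld_tokens)
            field_positions[path] = base + len(raw_tokens) + self.gap_size
        for fld, stream in field_streams.items():
            table = self.postings.setdefault(fld, {})
            n_words = 0
            for token in stream:
                if token.kind == "word":
                    n_words += 1
                table.setdefault(token.norm, {}).setdefault(record.doc_id, []).append(
                    token.position
                )
            self.doc_len.setdefault(fld, {})[record.doc_id] = n_words
        for table in self.postings.values():
            for docs in table.values():
                for positions in docs.values():
                    positions.sort()

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    def avg_doc_len(self, fld: str) -> float:
        lengths = self.doc_len.get(fld, {})
        if not lengths:
            return 0.0
        return sum(lengths.values()) / len(lengths)

    # -- scoring

    def _idf(self, fld: str, term: str) -> float:
        df = len(self.postings.get(fld, {}).get(term, {}))
        return math.log(1.0 + (self.n_docs - df + 0.5) / (df + 0.5))

    def bm25(self, fld: str, term: str, doc_id: str) -> float:
        positions = self.postings.get(fld, {}).get(term, {}).get(doc_id)
        if not positions:
            return 0.0
        tf = len(positions)
        dl = self.doc_len.get(fld, {}).get(doc_id, 0)
        avgdl = self.avg_doc_len(fld) or 1.0
        norm = tf * (BM25_K1 + 1) / (tf + BM25_K1 * (1 - BM25_B + BM25_B * dl / avgdl))
        return self._idf(fld, term) * norm

    # -- serialization

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        header = {
            "analyzer": {
                "lowercase": self.analyzer.lowercase,
                "stop_filter": self.analyzer.stop_filter,
                "stemmer": self.analyzer.stemmer,
                "stopwords": sorted(self.analyzer.stopwords),
            },
            "gap_size": self.gap_size,
            "doc_ids": self.doc_ids,
            "doc_len": self.doc_len,
        }
        with open(os.path.join(directory, "header.json"), "w", encoding="utf-8") as fh:
            json.dump(header, fh, sort_keys=True)
        with open(os.path.join(directory, "postings.json"), "w", encoding="utf-8") as fh:
            json.dump(self.postings, fh, sort_keys=True)

    @classmethod
    def load(cls, directory: str) -> "Index":
        with open(os.path.join(directory, "header.json"), encoding="utf-8") as fh:
            header = json.load(fh)
        analyzer = AnalyzerConfig(
            lowercase=header["analyzer"]["lowercase"],
            stop_filter=header["analyzer"]["stop_filter"],
            stemmer=header["analyzer"]["stemmer"],
            stopwords=frozenset(header["analyzer"]["stopwords"]),
        )
        index = cls(analyzer=analyzer, gap_size=header["gap_size"])
        index.doc_ids = list(header["doc_ids"])
        index.doc_len = {f: dict(d) for f, d in header["doc_len"].items()}
        with open(os.path.join(directory, "postings.json"), encoding="utf-8") as fh:
            index.postings = json.load(fh)
        return index


def build_index(
    records: list[MetadataRecord],
    gazetteer: Gazetteer | None = None,
    ontology: Ontology | None = None,
    analyzer: AnalyzerConfig | None = None,
    include_ancestors: bool = True,
    gap_size: int = DEFAULT_GAP_SIZE,
) -> Index:
    index = Index(analyzer=analyzer, gap_size=gap_size)
    for record in records:
        index.add_record(record, gazetteer, ontology, include_ancestors)
    return index


# ---------------------------------------------------------------------------
# Query execution


def _phrase_match(position_lists: list[list[int]], slop: int) -> bool:
    """True if an increasing assignment exists with span width - m <= slop."""
    m = len(position_lists)
    for p0 in position_lists[0]:
        prev = p0
        ok = True
        for positions in position_lists[1:]:
            # smallest position strictly after prev minimizes final width
            nxt = next((p for p in positions if p > prev), None)
            if nxt is None:
                ok = False
                break
            prev = nxt
        if ok and (prev - p0 + 1) - m <= slop:
            return True
    return False


def _eval(node: QueryNode, index: Index) -> dict[str, tuple[float, int]]:
    """Evaluate a node to ``{doc_id: (score, matched_immediate_clauses)}``."""
    if isinstance(node, Term):
        if node.field not in index.postings:
            raise IndexError_(f"unknown field {node.field!r}")
        term = index.analyzer.norm(node.text)
        docs = index.postings[node.field].get(term, {})
        return {d: (index.bm25(node.field, term, d) * node.boost, 1) for d in docs}
    if isinstance(node, ConceptQuery):
        if node.field not in index.postings:
            raise IndexError_(f"unknown field {node.field!r}")
        term = implicit_token(node.concept_id) if node.implicit else node.concept_id
        docs = index.postings[node.field].get(term, {})
        return {d: (index.bm25(node.field, term, d) * node.boost, 1) for d in docs}
    if isinstance(node, Phrase):
        if node.field not in index.postings:
            raise IndexError_(f"unknown field {node.field!r}")
        terms = [index.analyzer.norm(t) for t in node.texts]
        tables = [index.postings[node.field].get(t, {}) for t in terms]
        if any(not table for table in tables):
            return {}
        candidates = set(tables[0])
        for table in tables[1:]:
            candidates &= set(table)
        out: dict[str, tuple[float, int]] = {}
        for doc_id in candidates:
            if _phrase_match([table[doc_id] for table in tables], node.slop):
                score = sum(index.bm25(node.field, t, doc_id) for t in terms)
                out[doc_id] = (score * node.boost, 1)
        return out
    if isinstance(node, And):
        child_results = [_eval(child, index) for child in node.children]
        if not child_results:
            return {}
        docs = set(child_results[0])
        for result in child_results[1:]:
            docs &= set(result)
        return {
            d: (
                sum(result[d][0] for result in child_results) * node.boost,
                len(child_results),
            )
            for d in docs
        }
    if isinstance(node, Or):
        child_results = [_eval(child, index) for child in node.children]
        acc: dict[str, tuple[float, int]] = {}
        for result in child_results:
            for doc_id, (score, _count) in result.items():
                prev_score, prev_count = acc.get(doc_id, (0.0, 0))
                acc[doc_id] = (prev_score + score, prev_count + 1)
        return {
            d: (score * node.boost, count)
            for d, (score, count) in acc.items()
            if count >= node.min_should_match
        }
    raise IndexError_(f"unknown query node type {type(node).__name__}")


def execute_query(node: QueryNode, index: Index, top_n: int = 1000) -> list[ScoredHit]:
    """Rank documents for a query tree; ties broken by ascending doc_id."""
    if top_n <= 0:
        raise IndexError_(f"top_n must be positive, got {top_n}")
    results = _eval(node, index)
    hits = [
        ScoredHit(doc_id=d, score=score, matched_clause_count=count)
        for d, (score, count) in results.items()
    ]
    hits.sort(key=lambda h: (-h.score, h.doc_id))
    return hits[:top_n]
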