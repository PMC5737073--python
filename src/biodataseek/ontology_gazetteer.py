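"""Controlled-vocabulary gazetteers and longest-match entity tagging.

Two dictionary sources are modelled: a MeSH-like hierarchical thesaurus
(concepts with preferred terms, synonyms and parent links) and a flat gene
registry (symbols and aliases, optionally case-sensitive). Both are compiled
into token-sequence gazetteers; tagging is a left-to-right scan in which the
longest dictionary phrase starting at a position wins and consumes its span.

Matching is deliberately literal: no stemming, no punctuation stripping, and
a dictionary term containing a dash only matches text that kept the dash
("tgf-beta" never matches "tgf beta"). Single-comma dictionary entries
("Muscle, Abdominal") are stored comma-free in both orders; entries with two
or more commas are kept untouched.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from enum import Enum

from ._tokenize import Token, tokenize

__all__ = [
    "Source",
    "Concept",
    "Ontology",
    "Gazetteer",
    "EntityMention",
    "OntologyError",
    "normalize_dictionary_term",
    "build_gazetteer",
    "tag_entities",
    "load_concepts_jsonl",
    "load_concepts_tsv",
]


class OntologyError(ValueError):
    pass


class Source(str, Enum):
    MESH_LIKE = "mesh_like"
    GENE = "gene"


@dataclass
class Concept:
    concept_id: str
    preferred_term: str
    synonyms: list[str] = field(default_factory=list)
    parent_ids: list[str] = field(default_factory=list)
    source: Source = Source.MESH_LIKE
    case_sensitive: bool = False

    def surface_forms(self) -> list[str]:
        return [self.preferred_term, *self.synonyms]


@dataclass(frozen=True)
class EntityMention:
    """A tagged span over a token stream (token indices, end exclusive)."""

    start: int
    end: int
    surface: str
    concept_ids: frozenset[tuple[str, str]]  # (concept_id, source value)
    explicit: bool = True

    def ids_for_source(self, source: Source) -> list[str]:
        return sorted(cid for cid, src in self.concept_ids if src == source.value)


class Ontology:
    """Concept store with acyclic parent links (hierarchy on mesh_like only)."""

    def __init__(self, concepts: list[Concept]):
        self.concepts: dict[str, Concept] = {}
        for concept in concepts:
            if concept.concept_id in self.concepts:
                raise OntologyError(f"duplicate concept_id {concept.concept_id!r}")
            if concept.source is Source.GENE and concept.parent_ids:
                raise OntologyError(
                    f"gene concept {concept.concept_id!r} must not carry parents"
                )
            self.concepts[concept.concept_id] = concept
        self._check_acyclic()
        self._children: dict[str, list[str]] = {}
        for concept in concepts:
            for parent in concept.parent_ids:
                self._children.setdefault(parent, []).append(concept.concept_id)

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(cid: str, stack: list[str]) -> None:
            if state.get(cid) == 1:
                raise OntologyError(f"parent cycle at {cid!r}: {' -> '.join(stack)}")
            if state.get(cid) == 2:
                return
            state[cid] = 1
            for parent in self.concepts.get(cid, Concept(cid, cid)).parent_ids:
                visit(parent, stack + [parent])
            state[cid] = 2

        for cid in self.concepts:
            visit(cid, [cid])

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def ancestors(self, concept_id: str) -> list[str]:
        """All ancestors through every parent path, deduplicated nearest-first."""
        concept = self.concepts.get(concept_id)
        if concept is None:
            raise OntologyError(f"unknown concept_id {concept_id!r}")
        if concept.source is Source.GENE:
            raise OntologyError(f"{concept_id!r} is a gene concept: no hierarchy")
        out: list[str] = []
        seen: set[str] = {concept_id}
        frontier = deque(concept.parent_ids)
        while frontier:
            next_frontier: deque[str] = deque()
            for cid in frontier:
                if cid in seen:
                    continue
                seen.add(cid)
                out.append(cid)
                parent = self.concepts.get(cid)
                if parent is not None:
                    next_frontier.extend(parent.parent_ids)
            frontier = next_frontier
        return out

    def descendants(self, concept_id: str) -> list[str]:
        """All concepts below *concept_id*, deduplicated nearest-first."""
        if concept_id not in self.concepts:
            raise OntologyError(f"unknown concept_id {concept_id!r}")
        out: list[str] = []
        seen: set[str] = {concept_id}
        frontier = deque(self._children.get(concept_id, []))
        while frontier:
            next_frontier: deque[str] = deque()
            for cid in frontier:
                if cid in seen:
                    continue
                seen.add(cid)
                out.append(cid)
                next_frontier.extend(self._children.get(cid, []))
            frontier = next_frontier
        return out


def normalize_dictionary_term(term: str) -> list[str]:
    """Expand comma-inverted dictionary entries.

    One comma ("A, B") yields the comma-free form and its inversion
    ("A B", "B A"); zero commas pass through; two or more commas are left
    untreated. Other punctuation is never touched.
    """
    if not term or not term.strip():
        raise OntologyError("empty dictionary term")
    term = term.strip()
    n_commas = term.count(",")
    if n_commas == 0 or n_commas >= 2:
        return [term]
    left, right = (part.strip() for part in term.split(","))
    if not left or not right:
        return [term]
    return [f"{left} {right}", f"{right} {left}"]


@dataclass
class Gazetteer:
    """Token-sequence lookup compiled from concepts.

    Case-insensitive entries (all mesh_like terms and non-case-sensitive gene
    terms) are keyed by lowercase token tuples; case-sensitive gene symbols by
    verbatim token tuples.
    """

    ci_entries: dict[tuple[str, ...], set[tuple[str, str]]] = field(default_factory=dict)
    cs_entries: dict[tuple[str, ...], set[tuple[str, str]]] = field(default_factory=dict)
    max_entry_length: int = 0

    def lookup(self, surface_tokens: list[Token]) -> set[tuple[str, str]]:
        """Ids for one candidate span (union of both case spaces)."""
        ci_key = tuple(t.lower for t in surface_tokens)
        cs_key = tuple(t.surface for t in surface_tokens)
        return self.ci_entries.get(ci_key, set()) | self.cs_entries.get(cs_key, set())

    def _add(self, surface: str, concept_id: str, source: Source, case_sensitive: bool) -> None:
        tokens = tokenize(surface)
        if not tokens:
            return
        if case_sensitive:
            key = tuple(t.surface for t in tokens)
            table = self.cs_entries
        else:
            key = tuple(t.lower for t in tokens)
            table = self.ci_entries
        table.setdefault(key, set()).add((concept_id, source.value))
        self.max_entry_length = max(self.max_entry_length, len(key))


def build_gazetteer(concepts: list[Concept]) -> Gazetteer:
    """Compile preferred terms and synonyms into a longest-match gazetteer."""
    gazetteer = Gazetteer()
    for concept in concepts:
        case_sensitive = concept.source is Source.GENE and concept.case_sensitive
        for raw_term in concept.surface_forms():
            for surface in normalize_dictionary_term(raw_term):
                gazetteer._add(surface, concept.concept_id, concept.source, case_sensitive)
    return gazetteer


def tag_entities(tokens: list[Token], gazetteer: Gazetteer) -> list[EntityMention]:
    """Leftmost-longest greedy tagging of a token stream.

    At each position the longest matching entry wins and its span is consumed,
    so the output mentions are non-overlapping and sorted by start. Two
    equal-length entries matching the same span contribute their ids to a
    single mention.
    """
    mentions: list[EntityMention] = []
    i = 0
    n = len(tokens)
    while i < n:
        best: tuple[int, set[tuple[str, str]]] | None = None
        max_len = min(gazetteer.max_entry_length, n - i)
        for length in range(max_len, 0, -1):
            ids = gazetteer.lookup(tokens[i : i + length])
            if ids:
                best = (length, ids)
                break
        if best is None:
            i += 1
            continue
        length, ids = best
        surface = " ".join(t.surface for t in tokens[i : i + length])
        mentions.append(
            EntityMention(
                start=i, end=i + length, surface=surface, concept_ids=frozenset(ids)
            )
        )
        i += length
    return mentions


# ---------------------------------------------------------------------------
# File dialects


def _concept_from_dict(payload: dict) -> Concept:
    return Concept(
        concept_id=str(payload["concept_id"]),
        preferred_term=str(payload["preferred_term"]),
        synonyms=[str(s) for s in payload.get("synonyms", [])],
        parent_ids=[str(p) for p in payload.get("parent_ids", [])],
        source=Source(payload.get("source", "mesh_like")),
        case_sensitive=bool(payload.get("case_sensitive", False)),
    )


def load_concepts_jsonl(path: str) -> list[Concept]:
    """One concept object per line."""
    concepts = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                concepts.append(_concept_from_dict(json.loads(line)))
            except (KeyError, ValueError) as exc:
                raise OntologyError(f"{path}:{lineno}: {exc}") from exc
    return concepts


def load_concepts_tsv(path: str) -> list[Concept]:
    """Columns: id, preferred, pipe-joined synonyms, pipe-joined parents, source, case flag."""
    concepts = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise OntologyError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
            cid, preferred, synonyms, parents, source, case_flag = cols
            concepts.append(
                Concept(
                    concept_id=cid,
                    preferred_term=preferred,
                    synonyms=[s for s in synonyms.split("|") if s],
                    parent_ids=[p for p in parents.split("|") if p],
                    source=Source(source),
                    case_sensitive=case_flag.lower() in {"1", "true", "yes"},
                )
            )
    return concepts


def write_concepts_jsonl(concepts: list[Concept], path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for concept in concepts:
            handle.write(
                json.dumps(
                    {
                        "concept_id": concept.concept_id,
                        "preferred_term": concept.preferred_term,
                        "synonyms": concept.synonyms,
                        "parent_ids": concept.parent_ids,
                        "source": concept.source.value,
                        "case_sensitive": concept.case_sensitive,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
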