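"""Natural-language query parsing, tagging, and query-AST construction.

A raw user query ("regulation of DNA repair related to the estrogen signaling
pathway in breast cancer patients") is normalized (species abbreviations,
Greek characters), stripped of head/tail boilerplate, tokenized, and filtered
through a customized stop/interstitial word list. Removed words split the
query into chunks; chunks are tagged against the concept gazetteers
(longest match first), then against field-value dictionaries, and whatever
remains becomes plain "other" terms.

Four query strategies are built from the tagged parse:

* **unigram** — OR over the kept tokens on the aggregated text field;
* **field-tagged** — phrases matched to structured-field values searched in
  those fields with per-field boosts;
* **embedding-expanded** — the field-tagged query plus nearest-neighbour
  expansion phrases at a damping boost;
* **concept-expanded** — a boolean AND of a concept part (per-concept
  sub-queries over words, phrase, explicit/implicit/descendant concept ids)
  and an "everything else" part, each under its own minimum-should-match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from ._tokenize import Token, tokenize
from .corpus_io import FieldValueDictionary, normalize_phrase
from .index_engine import And, ConceptQuery, Or, Phrase, QueryNode, Term
from .ontology_gazetteer import EntityMention, Gazetteer, Ontology, Source, tag_entities

__all__ = [
    "ParsedQuery",
    "QueryConfig",
    "ParseError",
    "normalize_query",
    "parse_query",
    "tag_parsed_query",
    "build_unigram_query",
    "build_field_tagged_query",
    "build_embedding_expanded_query",
    "build_concept_expanded_query",
    "load_mapping_file",
    "DEFAULT_BOOSTS",
    "DEFAULT_FIELD_BOOSTS",
    "DEFAULT_QUERY_STOPWORDS",
    "DEFAULT_SPECIES_MAP",
    "GREEK_MAP",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Default resources (all configurable)

_BASE_STOPWORDS = frozenset(
    """a about above after again against all am an and any are as at be because
    been before being below between both but by could did do does doing down
    during each few for from further had has have having he her here hers him
    his how i if in into is it its itself just me more most my no nor not now
    of off on once only or other our out over own same she should so some such
    than that the their them then there these they this those through to too
    under until up very was we were what when where which while who whom why
    will with you your""".split()
)

# common words across dataset-search queries, removed in addition to the base list
_QUERY_EXTRA_STOPWORDS = frozenset(
    "related versus role effect data dataset datasets studies study search find".split()
)

DEFAULT_QUERY_STOPWORDS = _BASE_STOPWORDS | _QUERY_EXTRA_STOPWORDS

# head/tail boilerplate stripped before tokenization (longest first)
DEFAULT_HEAD_PATTERNS = (
    "find data on",
    "find datasets on",
    "find datasets of",
    "find all datasets",
    "search for datasets on",
    "search for data on",
    "search for",
    "looking for",
    "datasets on",
    "data on",
)

DEFAULT_SPECIES_MAP = {
    "M. musculus": "Mus musculus",
    "D. melanogaster": "Drosophila melanogaster",
    "H. sapiens": "Homo sapiens",
    "E. coli": "Escherichia coli",
    "C. elegans": "Caenorhabditis elegans",
    "S. cerevisiae": "Saccharomyces cerevisiae",
    "R. norvegicus": "Rattus norvegicus",
    "D. rerio": "Danio rerio",
    "A. thaliana": "Arabidopsis thaliana",
    "X. laevis": "Xenopus laevis",
}

GREEK_MAP = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "π": "pi", "ρ": "rho",
    "σ": "sigma", "τ": "tau", "υ": "upsilon", "φ": "phi", "χ": "chi",
    "ψ": "psi", "ω": "omega",
    "Α": "Alpha", "Β": "Beta", "Γ": "Gamma", "Δ": "Delta", "Κ": "Kappa",
}

DEFAULT_BOOSTS = {
    "phrase": 20.0,
    "and_words": 0.5,
    "explicit_id": 1.0,
    "implicit_id": 0.5,
    "descendant_id": 1.0,
    "descendant_implicit_id": 0.5,
    "other_term": 2.0,
    "expansion": 0.3,
}

# per-field boosts for field-value tagged clauses: curated entity fields get
# full weight, keyword-like fields half, incidental fields 0.2
DEFAULT_FIELD_BOOSTS = {"curated": 1.0, "keyword": 0.5, "incidental": 0.2}
_CURATED_HINTS = ("disease", "gene", "organism", "species", "treatment.agent")
_KEYWORD_HINTS = ("keyword", "tag", "subject")


def default_field_boost(field_path: str) -> float:
    lowered = field_path.lower()
    if any(h in lowered for h in _CURATED_HINTS):
        return DEFAULT_FIELD_BOOSTS["curated"]
    if any(h in lowered for h in _KEYWORD_HINTS):
        return DEFAULT_FIELD_BOOSTS["keyword"]
    return DEFAULT_FIELD_BOOSTS["incidental"]


# ---------------------------------------------------------------------------
# Types


@dataclass
class ParsedQuery:
    """A segmented, filtered, and (optionally) tagged query."""

    original: str
    kept_tokens: list[str] = field(default_factory=list)
    kept_surfaces: list[str] = field(default_factory=list)
    ignored_words: list[str] = field(default_factory=list)
    chunks: list[tuple[int, int]] = field(default_factory=list)
    mesh_mentions: list[EntityMention] = field(default_factory=list)
    gene_mentions: list[EntityMention] = field(default_factory=list)
    field_tagged: list[tuple[str, str, float]] = field(default_factory=list)
    field_tagged_spans: list[tuple[int, int]] = field(default_factory=list)
    other_terms: list[str] = field(default_factory=list)

    def chunk_text(self, span: tuple[int, int]) -> str:
        return " ".join(self.kept_tokens[span[0] : span[1]])


@dataclass(frozen=True)
class QueryConfig:
    """Toggles, boosts and minimum-should-match settings for query construction."""

    check_mesh: bool = True
    check_genes: bool = True
    include_implicit: bool = True
    include_descendants: bool = True
    boosts: tuple[tuple[str, float], ...] = tuple(sorted(DEFAULT_BOOSTS.items()))
    msm_concept_part: int | str = "all"  # absolute count or "all"
    msm_other_part: int | str = "all"
    slop: int = 0
    plural_strip: bool = False

    def boost(self, name: str) -> float:
        return dict(self.boosts)[name]

    def with_boosts(self, **overrides: float) -> "QueryConfig":
        merged = dict(self.boosts)
        merged.update(overrides)
        return replace(self, boosts=tuple(sorted(merged.items())))


# ---------------------------------------------------------------------------
# Normalization and parsing


def load_mapping_file(path: str) -> dict[str, str]:
    """Two-column TSV mapping file (source, replacement)."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2 or not cols[0] or not cols[1]:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
            mapping[cols[0]] = cols[1]
    return mapping


def normalize_query(
    text: str,
    species_map: dict[str, str] | None = None,
    greek_map: dict[str, str] | None = None,
) -> str:
    """Expand abbreviated species names and replace Greek characters.

    Species replacements are applied longest-source-first on word boundaries;
    Greek replacement is character-level. Everything else is untouched.
    """
    species_map = DEFAULT_SPECIES_MAP if species_map is None else species_map
    greek_map = GREEK_MAP if greek_map is None else greek_map
    for source in sorted(species_map, key=len, reverse=True):
        pattern = r"(?<!\w)" + re.escape(source) + r"(?!\w)"
        text = re.sub(pattern, species_map[source], text)
    if greek_map:
        text = "".join(greek_map.get(ch, ch) for ch in text)
    return text


def _strip_head_tail(text: str, head_patterns: tuple[str, ...]) -> str:
    stripped = text.strip().strip("?.!").strip()
    lowered = stripped.lower()
    for pattern in sorted(head_patterns, key=len, reverse=True):
        if lowered.startswith(pattern + " "):
            return stripped[len(pattern) + 1 :]
    return stripped


def parse_query(
    text: str,
    stopwords: frozenset[str] = DEFAULT_QUERY_STOPWORDS,
    head_patterns: tuple[str, ...] = DEFAULT_HEAD_PATTERNS,
) -> ParsedQuery:
    """Tokenize, filter stop/interstitial words, and segment into chunks.

    Removed words are recorded in order and each removal closes the current
    chunk; chunk spans are half-open over the kept-token sequence.
    """
    core = _strip_head_tail(text, head_patterns)
    parsed = ParsedQuery(original=text)
    chunk_start = 0
    for token in tokenize(core):
        if token.lower in stopwords:
            parsed.ignored_words.append(token.lower)
            if chunk_start < len(parsed.kept_tokens):
                parsed.chunks.append((chunk_start, len(parsed.kept_tokens)))
            chunk_start = len(parsed.kept_tokens)
            continue
        parsed.kept_tokens.append(token.lower)
        parsed.kept_surfaces.append(token.surface)
    if chunk_start < len(parsed.kept_tokens):
        parsed.chunks.append((chunk_start, len(parsed.kept_tokens)))
    if not parsed.kept_tokens:
        raise ParseError(f"no content terms in query {text!r}")
    return parsed


# ---------------------------------------------------------------------------
# Tagging


def _mention_source(mention: EntityMention) -> Source:
    # precedence: mesh over gene when a surface is ambiguous between sources
    if any(src == Source.MESH_LIKE.value for _cid, src in mention.concept_ids):
        return Source.MESH_LIKE
    return Source.GENE


def tag_parsed_query(
    parsed: ParsedQuery,
    gazetteer: Gazetteer | None = None,
    fv_dictionary: FieldValueDictionary | None = None,
    field_boost=default_field_boost,
) -> ParsedQuery:
    """Tag chunks with gazetteer concepts, then field values, then leftovers.

    Precedence is mesh > gene > field-value > other; every kept token ends up
    in exactly one bucket. Returns *parsed* mutated in place (and for
    convenience).
    """
    parsed.mesh_mentions = []
    parsed.gene_mentions = []
    parsed.field_tagged = []
    parsed.field_tagged_spans = []
    parsed.other_terms = []
    for chunk_start, chunk_end in parsed.chunks:
        tokens = [
            Token(parsed.kept_surfaces[i], parsed.kept_tokens[i], -1, -1)
            for i in range(chunk_start, chunk_end)
        ]
        mentions = tag_entities(tokens, gazetteer) if gazetteer is not None else []
        covered: set[int] = set()
        for mention in mentions:
            shifted = EntityMention(
                start=mention.start + chunk_start,
                end=mention.end + chunk_start,
                surface=mention.surface,
                concept_ids=mention.concept_ids,
            )
            covered.update(range(mention.start, mention.end))
            if _mention_source(mention) is Source.MESH_LIKE:
                parsed.mesh_mentions.append(shifted)
            else:
                parsed.gene_mentions.append(shifted)
        # field-value tagging over untagged spans, longest match first
        free = [i for i in range(len(tokens)) if i not in covered]
        runs: list[list[int]] = []
        for i in free:
            if runs and runs[-1][-1] == i - 1:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            i = 0
            while i < len(run):
                matched = False
                if fv_dictionary is not None:
                    for length in range(len(run) - i, 0, -1):
                        phrase = " ".join(
                            parsed.kept_tokens[chunk_start + run[i + j]]
                            for j in range(length)
                        )
                        fields = fv_dictionary.lookup(phrase)
                        if fields:
                            for path in sorted(fields):
                                parsed.field_tagged.append(
                                    (phrase, path, field_boost(path))
                                )
                            parsed.field_tagged_spans.append(
                                (
                                    chunk_start + run[i],
                                    chunk_start + run[i + length - 1] + 1,
                                )
                            )
                            i += length
                            matched = True
                            break
                if not matched:
                    term = parsed.kept_tokens[chunk_start + run[i]]
                    parsed.other_terms.append(_maybe_singular(term, False))
                    i += 1
    return parsed


def _maybe_singular(term: str, plural_strip: bool) -> str:
    if plural_strip and len(term) > 3 and term.endswith("s") and not term.endswith("ss"):
        return term[:-1]
    return term


# ---------------------------------------------------------------------------
# Query builders


def build_unigram_query(parsed: ParsedQuery) -> QueryNode:
    """OR over the kept tokens on the aggregated text field."""
    children = tuple(Term(text=token) for token in parsed.kept_tokens)
    if len(children) == 1:
        return children[0]
    return Or(children=children, min_should_match=1)


def _phrase_or_term(words: list[str], fld: str, boost: float, slop: int = 0) -> QueryNode:
    if len(words) == 1:
        return Term(text=words[0], field=fld, boost=boost)
    return Phrase(texts=tuple(words), field=fld, slop=slop, boost=boost)


def build_field_tagged_query(parsed: ParsedQuery) -> QueryNode:
    """Field-restricted phrase clauses for tagged values, unigrams elsewhere.

    With no field-tagged phrases this degrades to the unigram query.
    """
    if not parsed.field_tagged:
        return build_unigram_query(parsed)
    children: list[QueryNode] = []
    span_at_start = {span[0]: span for span in parsed.field_tagged_spans}
    in_phrase = {
        i for start, end in parsed.field_tagged_spans for i in range(start, end)
    }
    by_phrase: dict[str, list[tuple[str, float]]] = {}
    for phrase, path, boost in parsed.field_tagged:
        by_phrase.setdefault(phrase, []).append((path, boost))
    for i, token in enumerate(parsed.kept_tokens):
        if i in span_at_start:
            span = span_at_start[i]
            phrase = parsed.chunk_text(span)
            words = phrase.split()
            field_clauses = tuple(
                _phrase_or_term(words, path, boost) for path, boost in by_phrase[phrase]
            )
            children.append(
                field_clauses[0]
                if len(field_clauses) == 1
                else Or(children=field_clauses, min_should_match=1)
            )
        elif i not in in_phrase:
            children.append(Term(text=token))
    if len(children) == 1:
        return children[0]
    return Or(children=tuple(children), min_should_match=1)


def build_embedding_expanded_query(
    parsed: ParsedQuery,
    expander,
    k: int = 5,
    config: QueryConfig | None = None,
) -> QueryNode:
    """Field-tagged query plus per-chunk nearest-neighbour expansion clauses.

    Expansion candidates with underscores become phrase nodes; all expansion
    clauses carry the (sub-unit) expansion boost so they can only ever add
    evidence, never outrank an original-phrase match.
    """
    config = config or QueryConfig()
    base = build_field_tagged_query(parsed)
    expansion_boost = config.boost("expansion")
    extra: list[QueryNode] = []
    for span in parsed.chunks:
        chunk = parsed.chunk_text(span)
        result = expander.expand(chunk.replace(" ", "_"), k)
        for candidate, _sim in result.candidates:
            words = candidate.split("_")
            extra.append(_phrase_or_term(words, "", expansion_boost))
    if not extra:
        return base
    base_children = base.children if isinstance(base, Or) and base.min_should_match == 1 else (base,)
    return Or(children=tuple(base_children) + tuple(extra), min_should_match=1)


def _resolve_msm(value: int | str, n_children: int) -> int:
    if value == "all":
        return max(1, n_children)
    return max(1, min(int(value), n_children))


def _concept_subquery(
    mention: EntityMention,
    words: list[str],
    ontology: Ontology | None,
    config: QueryConfig,
    source: Source,
) -> QueryNode:
    clauses: list[QueryNode] = []
    if len(words) > 1:
        clauses.append(
            And(
                children=tuple(Term(text=w) for w in words),
                boost=config.boost("and_words"),
            )
        )
    clauses.append(_phrase_or_term(words, "", config.boost("phrase"), slop=config.slop))
    for concept_id in mention.ids_for_source(source):
        clauses.append(ConceptQuery(concept_id, boost=config.boost("explicit_id")))
        if source is Source.MESH_LIKE:
            if config.include_implicit:
                clauses.append(
                    ConceptQuery(
                        concept_id, implicit=True, boost=config.boost("implicit_id")
                    )
                )
            if config.include_descendants and ontology is not None and concept_id in ontology:
                for descendant in ontology.descendants(concept_id):
                    clauses.append(
                        ConceptQuery(descendant, boost=config.boost("descendant_id"))
                    )
                    if config.include_implicit:
                        clauses.append(
                            ConceptQuery(
                                descendant,
                                implicit=True,
                                boost=config.boost("descendant_implicit_id"),
                            )
                        )
    return Or(children=tuple(clauses), min_should_match=1)


def build_concept_expanded_query(
    parsed: ParsedQuery,
    ontology: Ontology | None = None,
    config: QueryConfig | None = None,
) -> QueryNode:
    """Boolean AND of the concept part and the everything-else part.

    The concept part ORs one sub-query per tagged MeSH-like concept or gene
    (original words AND'ed, the phrase form, and the explicit / implicit /
    descendant concept-id clauses); the other part ORs field-tagged phrases
    and the remaining terms. Each part carries its own minimum-should-match.
    """
    config = config or QueryConfig()
    part1: list[QueryNode] = []
    part2: list[QueryNode] = []

    def mention_words(mention: EntityMention) -> list[str]:
        return parsed.kept_tokens[mention.start : mention.end]

    for mention in parsed.mesh_mentions:
        words = mention_words(mention)
        if config.check_mesh:
            part1.append(
                _concept_subquery(mention, words, ontology, config, Source.MESH_LIKE)
            )
        else:
            part2.append(_phrase_words_clause(words, config))
    for mention in parsed.gene_mentions:
        words = mention_words(mention)
        if config.check_genes:
            part1.append(_concept_subquery(mention, words, None, config, Source.GENE))
        else:
            part2.append(_phrase_words_clause(words, config))

    seen_spans: set[tuple[int, int]] = set()
    for (phrase, _path, _boost), span in zip(
        parsed.field_tagged, _spans_for_phrases(parsed)
    ):
        if span in seen_spans:
            continue
        seen_spans.add(span)
        part2.append(_phrase_words_clause(phrase.split(), config))
    for term in parsed.other_terms:
        part2.append(
            Term(text=_maybe_singular(term, config.plural_strip), boost=config.boost("other_term"))
        )

    parts: list[QueryNode] = []
    if part1:
        parts.append(
            Or(
                children=tuple(part1),
                min_should_match=_resolve_msm(config.msm_concept_part, len(part1)),
            )
        )
    if part2:
        parts.append(
            Or(
                children=tuple(part2),
                min_should_match=_resolve_msm(config.msm_other_part, len(part2)),
            )
        )
    if not parts:
        raise ParseError("empty query: no concept or term clauses")
    if len(parts) == 1:
        return parts[0]
    return And(children=tuple(parts))


def _phrase_words_clause(words: list[str], config: QueryConfig) -> QueryNode:
    """AND-words + phrase form for a multiword phrase outside the concept part."""
    if len(words) == 1:
        return Term(text=words[0], boost=config.boost("phrase"))
    return Or(
        children=(
            And(children=tuple(Term(text=w) for w in words), boost=config.boost("and_words")),
            Phrase(texts=tuple(words), slop=config.slop, boost=config.boost("phrase")),
        ),
        min_should_match=1,
    )


def _spans_for_phrases(parsed: ParsedQuery) -> list[tuple[int, int]]:
    """Align field_tagged entries (one per (phrase, field)) with their spans."""
    spans: list[tuple[int, int]] = []
    span_by_phrase: dict[str, tuple[int, int]] = {}
    for span in parsed.field_tagged_spans:
        span_by_phrase[parsed.chunk_text(span)] = span
    for phrase, _path, _boost in parsed.field_tagged:
        spans.append(span_by_phrase[phrase])
    return spans
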