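"""Reading dataset-metadata records and deriving searchable text.

Dataset repositories export metadata as arbitrarily nested JSON. We flatten
each record to dotted field paths (``METADATA.Disease.name``), keep every
leaf value as a string, and build one aggregated text field holding all
values, the way a search engine would index "a single text field with all
values". Field-value dictionaries harvested from selected structured fields
drive exact-match tagging of query phrases.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

from ._tokenize import count_tokens

__all__ = [
    "MetadataRecord",
    "AggregatedText",
    "FieldValueDictionary",
    "CorpusError",
    "flatten_record",
    "build_aggregated_text",
    "build_field_value_dictionary",
    "load_corpus",
    "normalize_phrase",
]

DEFAULT_GAP_SIZE = 10

_WS_RE = re.compile(r"\s+")


class CorpusError(ValueError):
    """Raised for malformed corpus input (non-object records, duplicate ids)."""


def normalize_phrase(phrase: str) -> str:
    """Lowercase and collapse internal whitespace."""
    return _WS_RE.sub(" ", phrase.strip()).lower()


@dataclass
class MetadataRecord:
    """One dataset's flattened metadata.

    ``fields`` maps a dotted field path to the ordered list of string values
    observed at that path; ``all_text`` is the aggregation of every value.
    """

    doc_id: str
    fields: dict[str, list[str]]
    all_text: str = ""
    repository: str = ""


@dataclass
class AggregatedText:
    """Aggregated text plus the token-position offset of each field segment.

    Values are concatenated in sorted-field-path order (values within a field
    keep their original order). Consecutive values are separated by a
    positional gap so phrase and proximity queries cannot match across field
    boundaries.
    """

    text: str
    # (field_path, value, char_start, token_position_offset)
    segments: list[tuple[str, str, int, int]] = field(default_factory=list)


@dataclass
class FieldValueDictionary:
    """Exact-match dictionary of structured-field values.

    ``entries`` maps a normalized phrase to ``{field_path: document_frequency}``.
    """

    entries: dict[str, dict[str, int]] = field(default_factory=dict)
    source_fields: list[str] = field(default_factory=list)

    def lookup(self, phrase: str) -> dict[str, int]:
        return self.entries.get(normalize_phrase(phrase), {})


def _stringify_leaf(value: object) -> str | None:
    """JSON leaf to string; nulls dropped, booleans in JSON spelling."""
    if value is None:
        return None
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return json.dumps(value)
    return str(value)


def _walk(obj: object, path: str, out: dict[str, list[str]]) -> None:
    if isinstance(obj, dict):
        for key, val in obj.items():
            key = str(key)
            if not key:
                raise CorpusError(f"empty field-name segment under path {path!r}")
            _walk(val, f"{path}.{key}" if path else key, out)
    elif isinstance(obj, list):
        for element in obj:
            _walk(element, path, out)
    else:
        text = _stringify_leaf(obj)
        if text is not None:
            out.setdefault(path, []).append(text)


def flatten_record(
    raw: object, doc_id: str, gap_size: int = DEFAULT_GAP_SIZE, repository: str = ""
) -> MetadataRecord:
    """Flatten one raw JSON object into a :class:`MetadataRecord`.

    Nested objects become dot-joined paths; array elements share their parent
    path in order; scalars are stringified and nulls dropped. The aggregated
    ``all_text`` is built via :func:`build_aggregated_text`.
    """
    if not isinstance(raw, dict):
        raise CorpusError(
            f"record {doc_id!r}: top-level JSON value must be an object, "
            f"got {type(raw).__name__}"
        )
    fields: dict[str, list[str]] = {}
    _walk(raw, "", fields)
    record = MetadataRecord(doc_id=doc_id, fields=fields)
    record.all_text = build_aggregated_text(record, gap_size=gap_size).text
    return record


def build_aggregated_text(
    record: MetadataRecord, gap_size: int = DEFAULT_GAP_SIZE
) -> AggregatedText:
    """Concatenate all values deterministically with inter-value position gaps.

    Order is sorted field path, then original value order, so shared path
    prefixes (hierarchically related fields) land next to each other. Each
    segment records the token position at which its first token would sit;
    consecutive segments are ``gap_size`` empty positions apart so a phrase
    query with slop < gap_size can never straddle two values.
    """
    parts: list[str] = []
    segments: list[tuple[str, str, int, int]] = []
    position = 0
    char_pos = 0
    for path in sorted(record.fields):
        for value in record.fields[path]:
            if parts:
                char_pos += 1  # joining space
            segments.append((path, value, char_pos, position))
            parts.append(value)
            char_pos += len(value)
            position += count_tokens(value) + gap_size
    return AggregatedText(text=" ".join(parts), segments=segments)


def build_field_value_dictionary(
    corpus: list[MetadataRecord], field_paths: list[str]
) -> FieldValueDictionary:
    """Harvest every distinct value of the listed fields into a lookup table.

    Unknown field paths produce a warning and are skipped.
    """
    observed: set[str] = set()
    for record in corpus:
        observed.update(record.fields)
    kept_paths = []
    for path in field_paths:
        if path not in observed:
            warnings.warn(f"field path {path!r} not present in corpus; skipped")
            continue
        kept_paths.append(path)

    entries: dict[str, dict[str, int]] = {}
    for record in corpus:
        seen: set[tuple[str, str]] = set()  # df counts documents, not values
        for path in kept_paths:
            for value in record.fields.get(path, []):
                key = normalize_phrase(value)
                if not key or (key, path) in seen:
                    continue
                seen.add((key, path))
                entries.setdefault(key, {})
                entries[key][path] = entries[key].get(path, 0) + 1
    return FieldValueDictionary(entries=entries, source_fields=kept_paths)


def load_corpus(
    path: str,
    id_path: str = "_id",
    gap_size: int = DEFAULT_GAP_SIZE,
    repository_path: str | None = None,
) -> list[MetadataRecord]:
    """Load a JSON Lines corpus (one record per line).

    ``doc_id`` is taken from the configured top-level path, falling back to
    the 1-based line number; duplicate ids raise :class:`CorpusError`.
    """
    records: list[MetadataRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            raw = json.loads(line)
            doc_id = str(raw.get(id_path, lineno)) if isinstance(raw, dict) else str(lineno)
            if doc_id in seen:
                raise CorpusError(f"duplicate doc_id {doc_id!r} at line {lineno}")
            seen.add(doc_id)
            repository = ""
            if repository_path and isinstance(raw, dict):
                repository = str(raw.get(repository_path, ""))
            records.append(flatten_record(raw, doc_id, gap_size=gap_size, repository=repository))
    return records
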