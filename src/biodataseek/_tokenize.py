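"""Dash-preserving word tokenization shared by the tagger and the index analyzer.

A token is a maximal run of word characters, optionally joined by internal
dashes ("tgf-beta" is one token, distinct from the two tokens "tgf beta").
This makes the dash rule of dictionary matching fall out of tokenization:
a dictionary surface containing a dash can only ever match text that kept
the dash.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_TOKEN_RE = re.compile(r"\w+(?:-\w+)*", re.UNICODE)


@dataclass(frozen=True)
class Token:
    """A raw token with surface form, lowercase form and character offsets."""

    surface: str
    lower: str
    char_start: int
    char_end: int


def tokenize(text: str) -> list[Token]:
    """Split *text* into dash-preserving word tokens with character offsets."""
    return [
        Token(m.group(0), m.group(0).lower(), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


def count_tokens(text: str) -> int:
    return sum(1 for _ in _TOKEN_RE.finditer(text))
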