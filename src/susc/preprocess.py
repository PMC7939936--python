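"""Tokenization and normalization of clinical report text.

Bacterial culture and antimicrobial susceptibility reports arrive as loosely
structured free text.  Downstream detection and correction operate on
normalized word forms: lowercase, letters only.  No morphological stemming is
applied — species epithets ("aureus", "pyogenes") would be corrupted by any
general-purpose stemmer, and the terms of interest are full forms.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

__all__ = ["Token", "normalize", "tokenize"]

_WORD_RUN = re.compile(r"[\w'-]+")
_NON_LETTER = re.compile(r"[^a-z]")


@dataclass(frozen=True)
class Token:
    """A surface word with its normalized form and document position.

    Attributes
    ----------
    surface:
        The word exactly as it appeared in the text.
    normalized:
        Lowercased alphabetic form (a-z only), never empty.
    position:
        0-based ordinal index of the token within the document.
    start, end:
        Character offsets of the surface run in the source text, used to
        splice corrections back into the document byte-for-byte.
    """

    surface: str
    normalized: str
    position: int
    start: int = -1
    end: int = -1


def normalize(surface: str) -> str:
    """Normalize a surface word to a lowercase alphabetic form.

    Lowercases, strips accents where a plain-ASCII letter remains (bacterial
    nomenclature is ASCII), removes internal hyphens and apostrophes, and
    drops every remaining non-letter.  Returns ``""`` when nothing survives
    (digit runs, pure punctuation, untransliterable scripts).
    """
    s = unicodedata.normalize("NFKD", surface)
    s = s.encode("ascii", "ignore").decode("ascii")
    s = s.lower()
    return _NON_LETTER.sub("", s)


def tokenize(text: str) -> list[Token]:
    """Split free text into normalized tokens in reading order.

    Surface tokens are maximal runs of word characters (hyphens and
    apostrophes are kept inside a run, then removed by normalization).
    Runs whose normalized form is empty — digits, punctuation — are dropped.
    Empty input yields an empty list.
    """
    tokens: list[Token] = []
    for m in _WORD_RUN.finditer(text):
        norm = normalize(m.group())
        if not norm:
            continue
        tokens.append(
            Token(
                surface=m.group(),
                normalized=norm,
                position=len(tokens),
                start=m.start(),
                end=m.end(),
            )
        )
    return tokens
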