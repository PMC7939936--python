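"""Reference terminology and out-of-lexicon misspelling detection.

A lexicon is any plain-text list of accepted terms (in practice a slice of a
clinical terminology such as SNOMED CT, which cannot be redistributed and is
therefore always user-supplied).  Detection is purely set membership on
normalized forms: a token that fails to map to the lexicon is flagged as a
typographical error.  No fuzzy matching happens at detection time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .preprocess import Token, normalize

__all__ = ["Lexicon", "load_lexicon", "detect_misspellings", "MIN_DETECT_LEN"]

logger = logging.getLogger(__name__)

#: Tokens shorter than this many letters are never flagged: one- and
#: two-letter forms are abbreviations ("E", "sp"), not correctable targets.
MIN_DETECT_LEN = 3


@dataclass(frozen=True)
class Lexicon:
    """A set of accepted (correctly spelled) normalized terms."""

    terms: frozenset[str]
    name: str = "lexicon"

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("lexicon must contain at least one term")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_terms(cls, terms: Iterable[str], name: str = "lexicon") -> "Lexicon":
        """Build a lexicon from raw terms, normalizing and deduplicating."""
        normed = {normalize(t) for t in terms}
        normed.discard("")
        return cls(terms=frozenset(normed), name=name)


def load_lexicon(path: str | Path, name: str | None = None) -> Lexicon:
    """Load a lexicon from a UTF-8 text file, one term per line.

    Blank lines and lines starting with ``#`` are ignored; terms are
    normalized and deduplicated.  Raises ``FileNotFoundError`` for a missing
    file and ``ValueError`` if no terms survive (an empty lexicon would flag
    every token, which is never what the caller wants).
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8").splitlines()
    terms = [ln.strip() for ln in raw if ln.strip() and not ln.lstrip().startswith("#")]
    lex = Lexicon.from_terms(terms, name=name or path.name)
    logger.info("loaded %d terms from %s", len(lex), path)
    return lex


def detect_misspellings(
    tokens: list[Token], lexicon: Lexicon, min_len: int = MIN_DETECT_LEN
) -> list[Token]:
    """Return the tokens flagged as misspellings, in document order.

    A token is flagged when its normalized form has at least ``min_len``
    letters and is not a member of the lexicon.  Membership is exact string
    equality on normalized forms.
    """
    return [
        t
        for t in tokens
        if len(t.normalized) >= min_len and t.normalized not in lexicon.terms
    ]
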