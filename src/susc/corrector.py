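"""Candidate generation, ranking, and document correction.

The correction pipeline for one flagged token:

1. Retrieve the ``top_k`` nearest embedding neighbors of the misspelling
   (retrieval size comes first: a correct word outside the top-k neighbor
   list is unreachable by design).
2. Filter: cosine similarity >= ``cos_min``; edit distance <= ``dl_max``;
   length difference <= ``len_window``; not in the general-English stoplist;
   and — when the misspelling itself is in-vocabulary — the candidate must be
   *more frequent* (lower rank) than the misspelling, on the assumption that
   correctly spelled words dominate a large corpus.
3. Rank survivors by similarity descending, breaking near-ties by frequency
   rank, and take the top candidate as the correction.

The whole path is deterministic: no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Optional, Sequence

import pandas as pd

from .distance import damerau_levenshtein
from .embeddings import EmbeddingStore, OOVError, most_similar
from .lexicon import Lexicon, detect_misspellings
from .preprocess import Token, tokenize

__all__ = [
    "CorrectionParams",
    "Candidate",
    "CorrectionResult",
    "generate_candidates",
    "rank_candidates",
    "correct_token",
    "correct_document",
    "grid_search",
]

#: Similarity differences below this are treated as ties during ranking.
_SIM_TIE_EPS = 1e-9


@dataclass(frozen=True)
class CorrectionParams:
    """Hyperparameters of candidate generation and ranking.

    Defaults are the operating point used for bacterial culture reports:
    30 neighbors, cosine at least 0.80, at most 3 edits.

    Attributes
    ----------
    top_k:
        Neighbor retrieval size (how many most-similar words are considered).
    cos_min:
        Minimum cosine similarity a candidate must reach.
    dl_max:
        Maximum Damerau-Levenshtein distance (OSA) to the misspelling.
    max_rank:
        Optional vocabulary-rank cutoff restricting the neighbor search to
        the most frequent words.
    len_window:
        Maximum allowed absolute length difference; defaults to ``dl_max``
        (an edit budget of e can change length by at most e).
    require_more_frequent:
        If true, an in-vocabulary misspelling only accepts candidates that
        are more frequent than itself; vacuous for OOV misspellings.
    stoplist:
        General-English terms excluded from candidacy.
    """

    top_k: int = 30
    cos_min: float = 0.80
    dl_max: int = 3
    max_rank: Optional[int] = None
    len_window: Optional[int] = None
    require_more_frequent: bool = True
    stoplist: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0.0 < self.cos_min <= 1.0:
            raise ValueError("cos_min must be in (0, 1]")
        if self.dl_max < 1:
            raise ValueError("dl_max must be >= 1")

    @property
    def effective_len_window(self) -> int:
        return self.dl_max if self.len_window is None else self.len_window


@dataclass(frozen=True)
class Candidate:
    """A scored correction proposal for one misspelling."""

    word: str
    similarity: float
    distance: int
    rank: int


@dataclass(frozen=True)
class CorrectionResult:
    """The final per-token decision: chosen correction plus the ranked field."""

    token: Token
    corrected: Optional[str]
    candidates: tuple[Candidate, ...]
    status: str  # "corrected" | "no_candidate" | "skipped_oov"


def generate_candidates(
    store: EmbeddingStore,
    word: str,
    params: CorrectionParams,
    lexicon: Optional[Lexicon] = None,
) -> list[Candidate]:
    """Retrieve and filter correction candidates for a misspelled word.

    Applies every active filter to the ``top_k`` neighbor list (see module
    docstring).  When a lexicon is supplied, candidates present in it are
    preferred: the lexicon acts as a filter only if it leaves at least one
    candidate, so it can never empty an otherwise viable set.

    Raises ``OOVError`` when the word cannot be resolved to a vector.
    """
    neighbors = most_similar(store, word, k=params.top_k, max_rank=params.max_rank)
    word_rank = store.rank(word) if word in store else None
    window = params.effective_len_window

    out: list[Candidate] = []
    for cand_word, sim in neighbors:
        if sim < params.cos_min:
            continue
        if abs(len(cand_word) - len(word)) > window:
            continue
        if cand_word in params.stoplist:
            continue
        dist = damerau_levenshtein(cand_word, word)
        if dist > params.dl_max:
            continue
        cand_rank = store.rank(cand_word)
        if params.require_more_frequent and word_rank is not None and cand_rank >= word_rank:
            continue
        out.append(Candidate(word=cand_word, similarity=sim, distance=dist, rank=cand_rank))

    if lexicon is not None:
        in_lex = [c for c in out if c.word in lexicon]
        if in_lex:
            out = in_lex
    return out


def rank_candidates(candidates: Sequence[Candidate]) -> list[Candidate]:
    """Order filtered candidates: similarity first, frequency as tie-break.

    A stable sort by similarity descending; candidates whose similarities
    differ by less than 1e-9 are tied and ordered by frequency rank
    ascending, then lexicographically.  Output is a permutation of input.
    """
    def key(c: Candidate) -> tuple[float, int, str]:
        # Quantize similarity so near-equal values compare equal and fall
        # through to the frequency tie-break.
        return (-round(c.similarity / _SIM_TIE_EPS) * _SIM_TIE_EPS, c.rank, c.word)

    return sorted(candidates, key=key)


def correct_token(
    store: EmbeddingStore,
    token: Token,
    params: CorrectionParams,
    lexicon: Optional[Lexicon] = None,
) -> CorrectionResult:
    """Produce the final correction decision for one flagged token."""
    try:
        ranked = rank_candidates(
            generate_candidates(store, token.normalized, params, lexicon)
        )
    except OOVError:
        return CorrectionResult(token=token, corrected=None, candidates=(), status="skipped_oov")
    if not ranked:
        return CorrectionResult(token=token, corrected=None, candidates=(), status="no_candidate")
    return CorrectionResult(
        token=token,
        corrected=ranked[0].word,
        candidates=tuple(ranked),
        status="corrected",
    )


def _match_case(template: str, word: str) -> str:
    """Carry the surface casing pattern of ``template`` onto ``word``."""
    if template.isupper() and len(template) > 1:
        return word.upper()
    if template[:1].isupper():
        return word.capitalize()
    return word


def correct_document(
    text: str,
    lexicon: Lexicon,
    store: EmbeddingStore,
    params: CorrectionParams = CorrectionParams(),
    apply_lexicon_filter: bool = False,
) -> tuple[str, list[CorrectionResult]]:
    """Detect and correct misspellings in a document.

    Returns the corrected text — identical to the input except that each
    flagged token with a successful correction is replaced in place, casing
    preserved — together with one ``CorrectionResult`` per flagged token.

    ``apply_lexicon_filter`` turns on the lexicon-preference filter during
    candidate generation (off by default: the method's point is working
    without a trusted dictionary of correct forms).
    """
    tokens = tokenize(text)
    flagged = detect_misspellings(tokens, lexicon)
    results = [
        correct_token(store, t, params, lexicon if apply_lexicon_filter else None)
        for t in flagged
    ]
    pieces: list[str] = []
    cursor = 0
    for res in results:
        if res.status != "corrected":
            continue
        tok = res.token
        pieces.append(text[cursor : tok.start])
        pieces.append(_match_case(tok.surface, res.corrected))
        cursor = tok.end
    pieces.append(text[cursor:])
    return "".join(pieces), results


def grid_search(
    store: EmbeddingStore,
    labeled_pairs: Sequence[tuple[str, str]],
    grid: dict[str, Iterable],
    base_params: CorrectionParams = CorrectionParams(),
    lexicon: Optional[Lexicon] = None,
) -> tuple[pd.DataFrame, CorrectionParams]:
    """Evaluate the correction rate over a hyperparameter grid.

    Parameters
    ----------
    labeled_pairs:
        (misspelling, truth) pairs — one per misspelling type.
    grid:
        Mapping from parameter name (``top_k``, ``cos_min``, ``dl_max``,
        optionally ``max_rank``) to the values to sweep.

    Returns
    -------
    (table, best):
        ``table`` has one row per combination with its type-level correction
        rate; ``best`` is the argmax combination (first in iteration order on
        ties — deterministic).
    """
    from .evaluation import correction_rate

    if not labeled_pairs:
        raise ValueError("labeled_pairs must be non-empty")
    names = list(grid)
    combos = list(product(*(list(grid[n]) for n in names)))
    if not combos:
        raise ValueError("grid must be non-empty")

    gold = dict(labeled_pairs)
    rows = []
    best: tuple[float, CorrectionParams] | None = None
    for combo in combos:
        params = replace(base_params, **dict(zip(names, combo)))
        predicted = {}
        for miss, _truth in labeled_pairs:
            try:
                ranked = rank_candidates(generate_candidates(store, miss, params, lexicon))
            except OOVError:
                ranked = []
            predicted[miss] = ranked[0].word if ranked else None
        rate = correction_rate(predicted, gold)
        rows.append({**dict(zip(names, combo)), "correction_rate": rate})
        if best is None or rate > best[0]:
            best = (rate, params)
    assert best is not None
    return pd.DataFrame(rows), best[1]
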