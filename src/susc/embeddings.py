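"""Frequency-ordered word embeddings with cosine nearest-neighbor search.

The store wraps a word2vec-text matrix (the format BioWordVec and fastText
``.vec`` files ship in) whose vocabulary order is taken as descending corpus
frequency — rank 0 is the most frequent word.  That rank order is a contract
inherited from the input file, not re-verified here, and it is what the
corrector's frequency constraint and tie-breaks key on.

Out-of-vocabulary queries are answered by character-n-gram composition when a
subword model is attached (fastText-style: a word's vector is the normalized
sum of its boundary-marked n-gram vectors); plain ``.vec`` matrices carry no
subword table, so OOV queries against them fail fast rather than silently
returning a zero vector that would poison every similarity downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "EmbeddingStore",
    "SubwordModel",
    "OOVError",
    "cosine",
    "load_word2vec_text",
    "save_word2vec_text",
    "query_vector",
    "most_similar",
    "char_ngrams",
    "fnv1a_32",
]

logger = logging.getLogger(__name__)


class OOVError(KeyError):
    """Raised when a query word is out of vocabulary and cannot be composed."""


def fnv1a_32(s: str) -> int:
    """32-bit FNV-1a hash of a string's UTF-8 bytes.

    Fixed algorithm and byte order so that n-gram bucket assignment — and
    hence every synthetic embedding — is reproducible across platforms.
    """
    h = 0x811C9DC5
    for byte in s.encode("utf-8"):
        h ^= byte
        h = (h * 0x01000193) & 0xFFFFFFFF
    return h


def char_ngrams(word: str, n_min: int, n_max: int) -> list[str]:
    """Character n-grams of ``<word>`` with fastText boundary markers."""
    marked = f"<{word}>"
    return [
        marked[i : i + n]
        for n in range(n_min, n_max + 1)
        for i in range(len(marked) - n + 1)
    ]


@dataclass(frozen=True)
class SubwordModel:
    """Character-n-gram vector table enabling OOV query composition.

    Each n-gram of a boundary-marked word hashes (FNV-1a) into one of
    ``buckets`` fixed unit vectors; a word's vector is the L2-normalized
    weighted sum of its n-gram vectors.  With ``inverse_length_weights`` each
    n-gram contributes with weight 1/n, so the short grams that survive an
    edit dominate the vector — this is what lets single-edit variants of a
    word stay highly similar to it, the way trained subword embeddings
    behave.
    """

    n_min: int
    n_max: int
    buckets: int
    bucket_vectors: np.ndarray  # shape (buckets, dimension)
    inverse_length_weights: bool = True

    def compose(self, word: str) -> np.ndarray:
        grams = char_ngrams(word, self.n_min, self.n_max)
        if not grams:
            raise OOVError(f"word {word!r} too short for n-gram composition")
        vec = np.zeros(self.bucket_vectors.shape[1])
        for g in grams:
            w = 1.0 / len(g) if self.inverse_length_weights else 1.0
            vec += w * self.bucket_vectors[fnv1a_32(g) % self.buckets]
        norm = np.linalg.norm(vec)
        if norm == 0.0:
            raise OOVError(f"n-gram composition of {word!r} cancelled to zero")
        return vec / norm


@dataclass
class EmbeddingStore:
    """Frequency-ordered vocabulary plus an L2-normalized vector matrix.

    ``vocab[i]`` has frequency rank ``i``; ``vectors[i]`` is its unit vector.
    Rows are normalized once at construction so cosine similarity reduces to
    a dot product.
    """

    vocab: list[str]
    vectors: np.ndarray
    subword_model: Optional[SubwordModel] = None

    def __post_init__(self) -> None:
        if len(self.vocab) != self.vectors.shape[0]:
            raise ValueError("vocab size and vector row count differ")
        if len(set(self.vocab)) != len(self.vocab):
            raise ValueError("vocabulary entries must be unique")
        if self.vectors.ndim != 2 or self.vectors.shape[1] < 1:
            raise ValueError("vectors must be a (n, d) matrix with d >= 1")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0.0):
            raise ValueError("embedding matrix contains an all-zero row")
        self.vectors = self.vectors / norms[:, None]
        self._rank = {w: i for i, w in enumerate(self.vocab)}

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.vocab)

    def __contains__(self, word: str) -> bool:
        return word in self._rank

    def rank(self, word: str) -> int:
        """Frequency rank of an in-vocabulary word (0 = most frequent)."""
        return self._rank[word]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity dot(u,v)/(|u||v|), clamped to [-1, 1].

    A zero-norm argument raises ``ValueError`` — it signals a corrupt
    embedding row, not a legitimate query.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def load_word2vec_text(
    path: str | Path, max_vocab: int | None = None
) -> EmbeddingStore:
    """Load a word2vec text-format matrix (header ``n d``, then word rows).

    Loads at most ``max_vocab`` rows in file order, preserving frequency
    rank.  Malformed rows (wrong field count, unparsable numbers, duplicate
    words, zero vectors) are skipped with a logged warning.  A missing file,
    a bad header, or zero surviving rows is a fatal error.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header!r}")
        n_declared, dim = int(header[0]), int(header[1])
        if dim < 1:
            raise ValueError(f"{path}: non-positive dimension {dim}")
        vocab: list[str] = []
        seen: set[str] = set()
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            if max_vocab is not None and len(vocab) >= max_vocab:
                break
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                logger.warning("%s:%d: expected %d fields, got %d — skipped",
                               path, lineno, dim + 1, len(parts))
                continue
            word = parts[0]
            try:
                vec = np.array(parts[1:], dtype=float)
            except ValueError:
                logger.warning("%s:%d: unparsable vector — skipped", path, lineno)
                continue
            if word in seen:
                logger.warning("%s:%d: duplicate word %r — skipped", path, lineno, word)
                continue
            if not np.any(vec):
                logger.warning("%s:%d: zero vector for %r — skipped", path, lineno, word)
                continue
            seen.add(word)
            vocab.append(word)
            rows.append(vec)
    if not rows:
        raise ValueError(f"{path}: no embedding rows loaded")
    if max_vocab is None and len(rows) != n_declared:
        logger.warning("%s: header declared %d rows, loaded %d", path, n_declared, len(rows))
    return EmbeddingStore(vocab=vocab, vectors=np.vstack(rows))


def save_word2vec_text(store: EmbeddingStore, path: str | Path, precision: int = 6) -> None:
    """Write a store as word2vec text, round-trippable at ``precision`` digits."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(store)} {store.dimension}\n")
        for word, vec in zip(store.vocab, store.vectors):
            nums = " ".join(f"{x:.{precision}f}" for x in vec)
            fh.write(f"{word} {nums}\n")


def query_vector(store: EmbeddingStore, word: str) -> np.ndarray:
    """Vector for a word: its matrix row, or a subword-composed vector if OOV.

    Raises ``OOVError`` for an OOV word when the store has no subword model;
    the caller decides whether to skip the token.
    """
    if not word:
        raise ValueError("query word must be non-empty")
    if word in store:
        return store.vectors[store.rank(word)]
    if store.subword_model is not None:
        return store.subword_model.compose(word)
    raise OOVError(f"{word!r} is out of vocabulary and no subword model is attached")


def most_similar(
    store: EmbeddingStore,
    word: str,
    k: int,
    max_rank: int | None = None,
) -> list[tuple[str, float]]:
    """Top-``k`` vocabulary neighbors of a word by cosine similarity.

    The query word itself is excluded.  When ``max_rank`` is given the scan
    is restricted to frequency ranks below it.  Results are sorted by
    similarity descending; ties break by frequency rank ascending, then
    lexicographically.  Propagates ``OOVError`` from ``query_vector``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q = query_vector(store, word)
    limit = len(store) if max_rank is None else min(max_rank, len(store))
    sims = store.vectors[:limit] @ q
    order = sorted(
        (i for i in range(limit) if store.vocab[i] != word),
        key=lambda i: (-sims[i], i, store.vocab[i]),
    )
    return [(store.vocab[i], float(np.clip(sims[i], -1.0, 1.0))) for i in order[:k]]
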