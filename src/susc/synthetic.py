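"""Synthetic fixtures: skewed corpora, misspelling injection, n-gram embeddings.

Everything the pipeline needs to be exercised end-to-end with no downloads:

* a generator of pseudo-Latin bacterial-style terms and a Zipf-skewed corpus
  sampler over a lexicon;
* a seeded misspelling injector producing errors at an exact edit distance,
  with the ground truth recorded per token — the observed error profile in
  real culture-report corpora has one dominant error type and a long tail of
  singletons, which the skewed sampling reproduces;
* a deterministic character-n-gram embedding builder in which
  orthographically similar words have high cosine similarity, standing in
  for a trained subword model such as BioWordVec.

All randomness flows through explicit seeds; identical inputs give
byte-identical fixtures on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .distance import damerau_levenshtein
from .embeddings import EmbeddingStore, SubwordModel, fnv1a_32
from .lexicon import Lexicon

__all__ = [
    "InjectionSpec",
    "REFERENCE_ERROR_PROFILE",
    "generate_misspelling",
    "make_term_lexicon",
    "make_fixture_corpus",
    "make_profile_corpus",
    "draw_error_counts",
    "build_ngram_embedding",
    "make_subword_model",
    "write_corpus",
]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"
_ALL_OPS = frozenset({"insert", "delete", "substitute", "transpose"})

#: Reference profile of the 16 misspelling types observed in a multi-year
#: audit of bacterial culture and antimicrobial susceptibility reports:
#: (misspelling, correct form, occurrence count).  One dominant type and a
#: long singleton tail; counts sum to 914.
REFERENCE_ERROR_PROFILE: tuple[tuple[str, str, int], ...] = (
    ("stapylococcus", "staphylococcus", 827),
    ("sstreptococcus", "streptococcus", 21),
    ("adecarboxylate", "adecarboxylata", 19),
    ("parpinfluenzae", "parainfluenzae", 18),
    ("papatyphi", "paratyphi", 7),
    ("pseudodiphthericum", "pseudodiphtheriticum", 6),
    ("urealyticm", "urealyticum", 5),
    ("chromogens", "chromogenes", 2),
    ("flavbacterium", "flavobacterium", 2),
    ("ferentum", "fermentum", 1),
    ("koneensis", "koreensis", 1),
    ("ochrobacterium", "ochrobactrum", 1),
    ("orytihabitans", "oryzihabitans", 1),
    ("shingobacterium", "sphingobacterium", 1),
    ("stacherbrandfii", "stackebrandtii", 1),
    ("perosis", "peroris", 1),
)


@dataclass(frozen=True)
class InjectionSpec:
    """How misspellings are injected into a fixture corpus.

    ``n_errors`` is the exact edit distance of every injected error (1-3,
    matching the range real report errors fall in); ``rate`` the fraction of
    eligible tokens misspelled; ``ops`` the allowed edit operations.
    """

    n_errors: int = 1
    ops: frozenset[str] = _ALL_OPS
    seed: int = 0
    rate: float = 0.05

    def __post_init__(self) -> None:
        if not 1 <= self.n_errors <= 3:
            raise ValueError("n_errors must be in 1..3")
        if not self.ops or not self.ops <= _ALL_OPS:
            raise ValueError(f"ops must be a non-empty subset of {sorted(_ALL_OPS)}")
        if not 0.0 < self.rate <= 1.0:
            raise ValueError("rate must be in (0, 1]")


def _apply_edit(word: str, op: str, rng: np.random.Generator) -> str:
    if op == "insert":
        i = int(rng.integers(0, len(word) + 1))
        return word[:i] + rng.choice(list(_ALPHABET)) + word[i:]
    if op == "delete":
        i = int(rng.integers(0, len(word)))
        return word[:i] + word[i + 1 :]
    if op == "substitute":
        i = int(rng.integers(0, len(word)))
        c = rng.choice([ch for ch in _ALPHABET if ch != word[i]])
        return word[:i] + c + word[i + 1 :]
    if op == "transpose":
        spots = [i for i in range(len(word) - 1) if word[i] != word[i + 1]]
        if not spots:  # e.g. "aaaa": fall back to a substitution
            return _apply_edit(word, "substitute", rng)
        i = int(rng.choice(spots))
        return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
    raise ValueError(f"unknown edit operation {op!r}")


def generate_misspelling(
    word: str,
    spec: InjectionSpec,
    avoid: Optional[Iterable[str]] = None,
    max_tries: int = 100,
) -> str:
    """Corrupt a word to exactly ``spec.n_errors`` edit distance from it.

    Applies ``n_errors`` random single edits drawn from ``spec.ops`` and
    verifies the result really sits at the requested Damerau-Levenshtein
    distance (edits can cancel), resampling on collision with the original,
    an ``avoid`` word (typically the lexicon), or a shorter distance.
    Deterministic given ``(word, spec)``.  Exhausting ``max_tries`` raises —
    the word is too short or the alphabet too small.
    """
    if len(word) <= spec.n_errors + 2:
        raise ValueError(
            f"word {word!r} too short to corrupt with {spec.n_errors} errors"
        )
    avoid_set = set(avoid) if avoid is not None else set()
    rng = np.random.default_rng([spec.seed, fnv1a_32(word)])
    ops = sorted(spec.ops)
    for _ in range(max_tries):
        out = word
        for _ in range(spec.n_errors):
            out = _apply_edit(out, ops[int(rng.integers(0, len(ops)))], rng)
        if out == word or out in avoid_set:
            continue
        if damerau_levenshtein(out, word) == spec.n_errors:
            return out
    raise RuntimeError(f"could not corrupt {word!r} in {max_tries} attempts")


_ONSETS = ("b", "c", "d", "f", "g", "h", "k", "l", "m", "n", "p", "r", "s",
           "t", "v", "z", "st", "str", "ch", "th", "ph", "cl", "br")
_VOWELS = ("a", "e", "i", "o", "u")
_CODAS = ("", "", "s", "r", "n", "m", "x")


def make_term_lexicon(n_terms: int = 100, seed: int = 0, min_len: int = 7) -> Lexicon:
    """Generate a lexicon of unique pseudo-Latin bacterial-style terms.

    Terms are built from consonant-vowel syllables ("stapharoma",
    "clenovirus"-like shapes), at least ``min_len`` letters so they stay
    eligible for injection at distances up to 3.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    terms: set[str] = set()
    while len(terms) < n_terms:
        n_syll = int(rng.integers(3, 6))
        w = "".join(
            rng.choice(_ONSETS) + rng.choice(_VOWELS) for _ in range(n_syll)
        ) + rng.choice(_CODAS)
        if len(w) >= min_len:
            terms.add(w)
    return Lexicon(terms=frozenset(terms), name=f"synthetic-{n_terms}-{seed}")


def make_fixture_corpus(
    lexicon: Lexicon, n_tokens: int, spec: InjectionSpec, zipf_s: float = 1.2
) -> tuple[list[str], pd.DataFrame]:
    """Sample a frequency-skewed token stream and inject misspellings.

    Terms are drawn under a Zipf law (exponent ``zipf_s``) over the lexicon,
    so a handful of head terms dominate; each occurrence of a term long
    enough to corrupt is misspelled with probability ``spec.rate``, every
    type using one fixed misspelling.  Because errors ride on the skewed
    term frequencies, the per-type error counts inherit the
    dominant-head/singleton-tail shape seen in real report corpora.

    Returns the observed token list and a gold table with columns
    ``position``, ``token`` (observed), ``truth``, ``was_misspelled``.
    """
    if len(lexicon) < 10:
        raise ValueError("lexicon must have at least 10 terms")
    terms = sorted(lexicon.terms)
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(terms)
    weights = np.arange(1, len(terms) + 1, dtype=float) ** -zipf_s
    weights /= weights.sum()

    misspelling_of: dict[str, str] = {}
    tokens: list[str] = []
    rows = []
    draws = rng.choice(len(terms), size=n_tokens, p=weights)
    corrupt = rng.random(n_tokens)
    for pos, (ti, u) in enumerate(zip(draws, corrupt)):
        truth = terms[ti]
        eligible = len(truth) > spec.n_errors + 2
        if eligible and u < spec.rate:
            if truth not in misspelling_of:
                misspelling_of[truth] = generate_misspelling(
                    truth, spec, avoid=lexicon.terms
                )
            observed, was_miss = misspelling_of[truth], True
        else:
            observed, was_miss = truth, False
        tokens.append(observed)
        rows.append((pos, observed, truth, int(was_miss)))
    gold = pd.DataFrame(rows, columns=["position", "token", "truth", "was_misspelled"])
    return tokens, gold


def make_profile_corpus(
    profile: Sequence[tuple[str, str, int]] = REFERENCE_ERROR_PROFILE,
) -> tuple[list[str], pd.DataFrame]:
    """Expand an error profile into a token stream of just the misspellings.

    Each (misspelling, truth, count) row is emitted ``count`` times, so the
    gold table's per-type counts reproduce the profile totals by
    construction (914 over 16 types for the reference profile).
    """
    tokens: list[str] = []
    rows = []
    for miss, truth, count in profile:
        for _ in range(count):
            rows.append((len(tokens), miss, truth, 1))
            tokens.append(miss)
    gold = pd.DataFrame(rows, columns=["position", "token", "truth", "was_misspelled"])
    return tokens, gold


def draw_error_counts(
    n_types: int, total: int, seed: int = 0, s: float = 1.6
) -> list[int]:
    """Draw skewed per-type error counts summing exactly to ``total``.

    Largest-remainder apportionment of Zipf weights (exponent ``s``) over a
    random type order; every type gets at least one occurrence.
    """
    if n_types < 1 or total < n_types:
        raise ValueError("need total >= n_types >= 1")
    rng = np.random.default_rng(seed)
    w = np.arange(1, n_types + 1, dtype=float) ** -s
    rng.shuffle(w)
    w /= w.sum()
    quota = w * (total - n_types)
    counts = np.floor(quota).astype(int) + 1
    remainder = total - int(counts.sum())
    for i in np.argsort(quota - np.floor(quota))[::-1][:remainder]:
        counts[i] += 1
    return counts.tolist()


def make_subword_model(
    dimension: int = 100,
    n_min: int = 1,
    n_max: int = 4,
    buckets: int = 2048,
    seed: int = 0,
) -> SubwordModel:
    """Deterministically construct the n-gram bucket-vector table.

    The same parameters always yield the same table, so a plain ``.vec``
    matrix written by :func:`build_ngram_embedding` can be re-attached to
    its subword model from a five-number sidecar spec.
    """
    rng = np.random.default_rng(seed)
    bucket_vectors = rng.standard_normal((buckets, dimension))
    bucket_vectors /= np.linalg.norm(bucket_vectors, axis=1)[:, None]
    return SubwordModel(
        n_min=n_min, n_max=n_max, buckets=buckets, bucket_vectors=bucket_vectors
    )


def build_ngram_embedding(
    words_with_freq: Sequence[tuple[str, float]],
    dimension: int = 100,
    n_min: int = 1,
    n_max: int = 4,
    buckets: int = 2048,
    seed: int = 0,
) -> EmbeddingStore:
    """Build a deterministic character-n-gram embedding over a vocabulary.

    Every n-gram of ``<word>`` (boundary markers, n in ``n_min..n_max``)
    hashes via FNV-1a to one of ``buckets`` fixed random unit vectors; a
    word's vector is the normalized sum of its n-gram vectors, each weighted
    1/n so that the short grams an edit cannot destroy dominate.  The vocab
    is ordered by descending supplied frequency (ties broken alphabetically)
    and the subword table is attached, so out-of-vocabulary queries compose
    the same way.
    """
    words = [w for w, _ in words_with_freq]
    if len(set(words)) != len(words):
        raise ValueError("words must be unique")
    if dimension < 16:
        raise ValueError("dimension must be >= 16")
    if not 1 <= n_min <= n_max <= 6:
        raise ValueError("need 1 <= n_min <= n_max <= 6")
    model = make_subword_model(
        dimension=dimension, n_min=n_min, n_max=n_max, buckets=buckets, seed=seed
    )
    ordered = sorted(words_with_freq, key=lambda wf: (-wf[1], wf[0]))
    vocab = [w for w, _ in ordered]
    vectors = np.vstack([model.compose(w) for w in vocab])
    return EmbeddingStore(vocab=vocab, vectors=vectors, subword_model=model)


def write_corpus(tokens: Sequence[str], gold: pd.DataFrame, out_dir: str | Path,
                 per_line: int = 12) -> None:
    """Write a fixture corpus as ``corpus.txt`` plus ``gold.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [
        " ".join(tokens[i : i + per_line]) for i in range(0, len(tokens), per_line)
    ]
    (out / "corpus.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    gold.to_csv(out / "gold.tsv", sep="\t", index=False)
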