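import numpy as np
import pytest

from susc.embeddings import EmbeddingStore
from susc.lexicon import Lexicon
from susc.synthetic import (
    REFERENCE_ERROR_PROFILE,
    build_ngram_embedding,
    make_term_lexicon,
)


@pytest.fixture(scope="session")
def profile_pairs() -> list[tuple[str, str]]:
    """(misspelling, truth) pairs of the 16-type reference error profile."""
    return [(m, t) for m, t, _ in REFERENCE_ERROR_PROFILE]


@pytest.fixture(scope="session")
def truth_lexicon() -> Lexicon:
    """Lexicon of the 16 correct spellings from the reference profile."""
    return Lexicon.from_terms(
        [t for _, t, _ in REFERENCE_ERROR_PROFILE], name="reference-truths"
    )


@pytest.fixture(scope="session")
def fixture_store() -> EmbeddingStore:
    """Synthetic n-gram embedding over the 16 truths plus 50 distractors.

    Truths get the profile occurrence counts as frequencies, distractors a
    unit frequency, so every truth outranks every distractor.
    """
    freqs = [(t, float(c)) for _, t, c in REFERENCE_ERROR_PROFILE]
    distractors = sorted(make_term_lexicon(50, seed=123).terms)
    freqs += [(w, 0.5) for w in distractors if w not in {t for _, t, _ in REFERENCE_ERROR_PROFILE}]
    return build_ngram_embedding(freqs, dimension=100, seed=0)


@pytest.fixture()
def orthogonal_store() -> EmbeddingStore:
    """Store whose 8 word vectors are mutually orthogonal basis vectors."""
    words = [f"word{c}" for c in "abcdefgh"]
    return EmbeddingStore(vocab=words, vectors=np.eye(8))


@pytest.fixture()
def vec_file(tmp_path):
    """Factory writing a word2vec text file from (word, vector) rows."""

    def _write(rows, dim=None, name="toy.vec", header=None):
        d = dim if dim is not None else len(rows[0][1])
        n, dd = header if header is not None else (len(rows), d)
        lines = [f"{n} {dd}"]
        for word, vec in rows:
            lines.append(word + " " + " ".join(str(x) for x in vec))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write
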