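# Methods

## Problem and model

Clinical culture reports contain long, low-frequency organism names that are
easily mistyped and that no affordable dictionary fully covers. `susc`
treats spelling correction as unsupervised nearest-neighbor search in a
subword embedding space: a corpus-trained character-n-gram embedding places
a misspelling close to its correct form (they share most of their n-grams
and their contexts), so the correction can be read off the neighbor list
without a dictionary of corrections.

Detection is deliberately crude and exact: a normalized token of at least 3
letters absent from the reference lexicon is a typographical error. The
lexicon is a membership oracle only — no concept identifiers, synonym
expansion, or phrase matching. One- and two-letter tokens are never flagged
because they are abbreviations ("E", "sp"), not correctable targets.

Correction applies four constraints to the top-k cosine neighbors of the
flagged word, then ranks survivors by similarity with frequency tie-breaks.
The constraints and their defaults:

| parameter | default | meaning |
|---|---|---|
| `top_k` | 30 | neighbor retrieval size; a correct form outside the top 30 neighbors is unreachable by design (retrieval happens before filtering) |
| `cos_min` | 0.80 | minimum cosine similarity (dimensionless, in (0, 1]) |
| `dl_max` | 3 | maximum Damerau–Levenshtein distance in edits; observed report errors all fall within 3 |
| `len_window` | = `dl_max` | maximum absolute length difference; an edit budget of e can change length by at most e |
| `require_more_frequent` | on | an in-vocabulary misspelling only accepts candidates of lower frequency rank, since correct forms dominate large corpora; vacuous for out-of-vocabulary misspellings |
| `stoplist` | empty | general-English words excluded from candidacy, so common words cannot hijack corrections of domain terms |
| `max_rank` | off | optional restriction of the neighbor scan to the most frequent vocabulary slice |

Ranking uses similarity as the primary key; similarities within 1e-9 are
treated as tied and ordered by frequency rank, then alphabetically, making
the pipeline fully deterministic. Whether frequency should enter as a
weighted score rather than a tie-break is genuinely open; the tie-break
reading is implemented because it keeps the two stated orderings
("sorted by similarity", "ranked considering frequency") consistent.
Real-word errors (valid embedding words absent from the lexicon) pass
through the identical path; they typically fail the similarity threshold
and surface as `no_candidate`, which is accepted behavior.

## Edit distance

The distance is the optimal-string-alignment (OSA) form of
Damerau–Levenshtein: insertions, deletions, substitutions, and adjacent
transpositions, with no substring edited twice. OSA is the standard
spell-checking variant and reproduces every audited correction-pair
distance. It is symmetric and non-negative with identity of indiscernibles,
but it is *not* a metric — the triangle inequality can fail (d("ca","abc")
= 3 > d("ca","ab") + d("ab","abc")) — so no algorithm in the package relies
on triangle pruning. Distances are always computed on normalized
(lowercase) forms. Correctness is checked two ways: an independent
recursive-definition oracle over all ~132k string pairs of length ≤ 5 on a
3-letter alphabet, and the printed distances of the 16 audited pairs.

Two quirks of the audited reference table are resolved in the package's
data: the dominant misspelling type is recorded as "stapylococcus" (its
listed frequency row prints the correct form, an evident typo), and the
"pseudodiphthericum" spelling is used for the distance-2 pair (the
alternative printed spelling computes to 3 under every standard variant).

## Normalization

Case folding, NFKD accent stripping to ASCII, removal of internal hyphens
and apostrophes, and deletion of all remaining non-letters. No morphological
stemming: stemmers corrupt species epithets, and all reference terms are
full forms. Tokens that normalize to nothing (digit runs, punctuation,
untransliterable scripts) are excluded from the token stream; in document
correction every byte outside a replaced token is preserved verbatim, so
such spans pass through untouched.

## Evaluation definitions

Type-level **correction rate** = corrected types / total types, with exact
string match. Token-level metrics over an aligned stream of (original,
truth, was_misspelled) gold rows versus final forms:

* accuracy — fraction of all tokens whose final form equals the truth;
* precision — among tokens the system changed, fraction changed to the
  truth; a system that changes nothing has precision 1 by convention
  (logged), so a do-nothing baseline scores high accuracy/precision with
  recall equal to 0;
* recall — among gold-misspelled tokens, fraction whose final form equals
  the truth;
* F1 — harmonic mean.

Displayed values are rounded to 2 decimals; internal values keep full
precision.

## Synthetic fixtures: what they emulate, what they do not

The synthetic module generates (a) pseudo-Latin bacterial-style term
lexicons from consonant-vowel syllables; (b) Zipf-skewed corpora (exponent
1.2, echoing the one-dominant-type / long-singleton-tail error profile
observed in real reports, where one type accounts for 827 of 914 errors);
(c) misspellings at an *exact* edit distance, verified by the distance
module and resampled on collision with the lexicon; and (d) a deterministic
character-n-gram embedding.

The embedding hashes each n-gram of the boundary-marked word (FNV-1a 32-bit,
fixed byte order) into one of 2048 fixed random unit vectors and takes the
normalized weighted sum. Defaults are n ∈ 1..4 with per-gram weight 1/n.
Short grams survive single edits almost unchanged, so weighting them up
reproduces the empirical signature of *trained* subword embeddings — a
single-edit variant of a 13-letter word keeps cosine ≈ 0.85–0.95 to its
source — whereas an unweighted 3–6-gram hash sum cannot: one interior edit
destroys up to 18 of ~46 grams and caps the cosine near 0.6, below any
useful threshold. With these defaults all 16 audited pairs sit at ≥ 0.86
while unrelated bacterial-style terms stay ≤ ~0.70, and words sharing no
n-grams concentrate near 0 by random-vector cancellation.

What the fixture does *not* emulate: distributional semantics (no
co-occurrence signal, so real-word errors cannot be modeled), trained
vector anisotropy, vocabulary scale (hundreds of words, not millions), and
corpus noise in the frequency ordering. Passing the end-to-end fixture test
therefore demonstrates that the pipeline's mechanics (detection, OOV
composition, filtering, ranking, evaluation) are correct under a faithful
orthographic-similarity structure — not that any particular correction rate
transfers to a real embedding and hospital corpus.

## Problem sizes and numerical choices

The standing end-to-end fixture uses a 100-term lexicon, 2000 tokens, 5%
injection at distance 1, embedding dimension 100, seed 0 — large enough for
~100 injected errors while the full suite runs in seconds. The oracle
cross-check enumerates all pairs over a 3-letter alphabet up to length 5.
Cosines are clamped to [−1, 1] against rounding; embedding rows are
L2-normalized once at load so similarity is a dot product; zero vectors are
rejected at load (a silent zero row would poison every similarity).
Grid-search iterates combinations in the given order and keeps the first
argmax, so results are reproducible. All randomness flows through explicit
integer seeds (numpy `default_rng`), and misspelling generation seeds per
word via the same FNV-1a hash, so fixtures are identical across platforms.

## Known limitations

* Detection is token-level membership; multi-word terms are matched word by
  word.
* A plain `.vec` matrix carries no subword table, so out-of-vocabulary
  misspellings are skipped (`skipped_oov`) unless a subword model is
  attached; the fastText binary format is not parsed.
* The frequency constraint assumes the embedding's vocabulary order really
  is descending corpus frequency; this contract is inherited from the input
  file, not verified.
* No context disambiguation: the same misspelling always receives the same
  correction regardless of surrounding words.
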