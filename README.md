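# susc — similarity-based unsupervised spelling correction

Bacterial culture and antimicrobial susceptibility reports are free text,
and the organism names in them ("Staphylococcus aureus", "Corynebacterium
pseudodiphtheriticum") are long, field-specific, and frequently mistyped.
Classic spell checkers need a curated dictionary of correct forms plus edit
distance; for clinical terminology such dictionaries are expensive and never
complete. `susc` implements the alternative: correct misspellings with a
**pretrained subword word embedding** instead of a dictionary.

The method, per flagged token *w*:

1. **Detection** — tokenize and normalize the report; any token of ≥ 3
   letters not found in a reference lexicon *L* (e.g. a SNOMED CT term
   slice) is flagged as a typographical error.
2. **Candidate generation** — retrieve the *k* nearest vocabulary words of
   *w* by cosine similarity from a frequency-ordered embedding matrix
   (fastText-style character-n-gram vectors handle out-of-vocabulary
   misspellings), then keep candidates *c* with

   cos(v_w, v_c) ≥ τ, DL(w, c) ≤ δ, |len(w) − len(c)| ≤ δ,
   rank(c) < rank(w),

   where DL is the Damerau–Levenshtein distance (optimal-string-alignment
   variant: insertions, deletions, substitutions, adjacent transpositions)
   and rank is frequency rank — a correctly spelled word should be more
   frequent than its misspelling in a large corpus. Defaults: k = 30,
   τ = 0.80, δ = 3.
3. **Ranking** — sort survivors by similarity, breaking near-ties by
   frequency rank; the top candidate is the correction.

Evaluation covers both the type-level **correction rate** (fraction of
distinct misspelling types corrected exactly) and token-level
accuracy/precision/recall/F1 over an aligned gold stream.

The package also ships a first-class synthetic module: pseudo-Latin term
lexicons, Zipf-skewed corpora with seeded misspelling injection at an exact
edit distance, and a deterministic character-n-gram embedding in which
orthographically similar words have high cosine similarity — everything
needed to exercise the full pipeline with no downloads.

## Worked example

```python
from susc import (CorrectionParams, Lexicon, build_ngram_embedding,
                  correct_document, REFERENCE_ERROR_PROFILE)

lexicon = Lexicon.from_terms(
    [t for _, t, _ in REFERENCE_ERROR_PROFILE] + ["aureus", "culture", "grew"])
store = build_ngram_embedding(
    [(t, float(c)) for _, t, c in REFERENCE_ERROR_PROFILE], seed=0)

report = "Culture grew Stapylococcus aureus; also sstreptococcus and perosis."
fixed, results = correct_document(report, lexicon, store, CorrectionParams())
print(fixed)
for r in results:
    top = r.candidates[0] if r.candidates else None
    print(f"{r.token.normalized:16s} -> {r.corrected!s:16s} status={r.status}"
          + (f" sim={top.similarity:.3f} dist={top.distance}" if top else ""))
```

prints

```
Culture grew Staphylococcus aureus; also streptococcus and peroris.
stapylococcus    -> staphylococcus   status=corrected sim=0.962 dist=1
also             -> None             status=no_candidate
sstreptococcus   -> streptococcus    status=corrected sim=0.982 dist=1
and              -> None             status=no_candidate
perosis          -> peroris          status=corrected sim=0.868 dist=1
```

All three injected misspellings are restored in place with casing
preserved. "also" and "and" are flagged only because the toy lexicon lacks
them, and correctly receive no candidate (this is what the optional
general-English stoplist and a fuller lexicon are for).

## Command line

```sh
susc distance stapylococcus staphylococcus      # -> 1
susc make-fixtures --out fx --seed 7            # lexicon, corpus, gold, .vec
susc detect  --lexicon fx/lexicon.txt fx/corpus.txt
susc correct --lexicon fx/lexicon.txt --embeddings fx/embedding.vec \
             --subword fx/subword.json --results out.jsonl fx/corpus.txt
susc evaluate --pred pred.jsonl --gold fx/gold.tsv
susc grid-search --pairs pairs.tsv --grid grid.json --embeddings fx/embedding.vec
```

Real embeddings in word2vec text format (e.g. BioWordVec `.vec`) load
directly via `--embeddings`; `--subword` attaches the deterministic
synthetic n-gram model so out-of-vocabulary misspellings can be composed.

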