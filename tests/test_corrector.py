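"""Candidate generation, ranking, document correction, grid search."""

import dataclasses

import pytest

from susc.corrector import (
    Candidate,
    CorrectionParams,
    correct_document,
    correct_token,
    generate_candidates,
    grid_search,
    rank_candidates,
)
from susc.distance import damerau_levenshtein
from susc.lexicon import Lexicon
from susc.preprocess import Token
from susc.synthetic import REFERENCE_ERROR_PROFILE


def tok(word: str, pos: int = 0) -> Token:
    return Token(surface=word, normalized=word, position=pos)


class TestParams:
    @pytest.mark.parametrize("kw", [{"top_k": 0}, {"cos_min": 0.0}, {"cos_min": 1.5}, {"dl_max": 0}])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            CorrectionParams(**kw)

    def test_len_window_defaults_to_dl_max(self):
        assert CorrectionParams(dl_max=2).effective_len_window == 2


class TestGenerateCandidates:
    def test_orthogonal_store_yields_nothing(self, orthogonal_store):
        assert generate_candidates(orthogonal_store, "worda", CorrectionParams()) == []

    def test_misspelling_yields_truth(self, fixture_store):
        cands = generate_candidates(fixture_store, "sstreptococcus", CorrectionParams())
        words = [c.word for c in cands]
        assert "streptococcus" in words
        match = next(c for c in cands if c.word == "streptococcus")
        assert match.distance == 1
        assert match.similarity >= 0.80

    def test_tight_len_window_empties_set(self, fixture_store):
        params = CorrectionParams(len_window=0)
        cands = generate_candidates(fixture_store, "sstreptococcus", params)
        # truth differs in length by 1, so it cannot survive a zero window
        assert all(len(c.word) == len("sstreptococcus") for c in cands)
        assert "streptococcus" not in [c.word for c in cands]

    def test_near_one_cosine_threshold_empties_set(self, fixture_store):
        params = CorrectionParams(cos_min=0.999999)
        assert generate_candidates(fixture_store, "stapylococcus", params) == []

    def test_stoplist_excludes_candidates(self, fixture_store):
        params = CorrectionParams(stoplist=frozenset({"streptococcus"}))
        cands = generate_candidates(fixture_store, "sstreptococcus", params)
        assert "streptococcus" not in [c.word for c in cands]

    def test_frequency_constraint_for_in_vocab_word(self, fixture_store):
        """An in-vocabulary query only accepts more frequent candidates."""
        word = "peroris"  # in vocab, frequency 1 => near the rank tail
        rank = fixture_store.rank(word)
        cands = generate_candidates(fixture_store, word, CorrectionParams(cos_min=0.01))
        assert all(c.rank < rank for c in cands)

    def test_lexicon_preference_is_filter_not_veto(self, fixture_store):
        lex = Lexicon.from_terms(["streptococcus"])
        params = CorrectionParams(cos_min=0.5)
        with_lex = generate_candidates(fixture_store, "sstreptococcus", params, lex)
        assert [c.word for c in with_lex] == ["streptococcus"]
        # a lexicon matching nothing leaves the candidate set untouched
        unrelated = Lexicon.from_terms(["zzzzzzz"])
        without = generate_candidates(fixture_store, "sstreptococcus", params, unrelated)
        assert [c.word for c in without] == [
            c.word for c in generate_candidates(fixture_store, "sstreptococcus", params)
        ]

    def test_all_filters_hold_posthoc(self, fixture_store, profile_pairs):
        """Independent audit: every emitted candidate satisfies every filter."""
        params = CorrectionParams()
        for miss, _ in profile_pairs:
            for c in generate_candidates(fixture_store, miss, params):
                assert c.similarity >= params.cos_min
                assert damerau_levenshtein(c.word, miss) <= params.dl_max
                assert abs(len(c.word) - len(miss)) <= params.effective_len_window
                assert c.rank == fixture_store.rank(c.word)


class TestRankCandidates:
    def test_empty(self):
        assert rank_candidates([]) == []

    def test_equal_similarity_breaks_by_frequency_rank(self):
        a = Candidate("lowrank", 0.9, 1, rank=5)
        b = Candidate("highfreq", 0.9, 1, rank=2)
        assert rank_candidates([a, b])[0] is b

    def test_agrees_with_sort_oracle(self):
        import random

        rng = random.Random(3)
        cands = [
            Candidate(f"w{i}", rng.choice([0.95, 0.9, 0.85]), 1, rank=rng.randrange(50))
            for i in range(10)
        ]
        expected = sorted(cands, key=lambda c: (-c.similarity, c.rank, c.word))
        assert rank_candidates(cands) == expected

    def test_permutation_of_input(self):
        cands = [Candidate(f"w{i}", 0.9 - i * 0.01, 1, rank=i) for i in range(6)]
        assert sorted(rank_candidates(cands), key=id) == sorted(cands, key=id)


class TestCorrectToken:
    def test_fixture_misspelling_corrected(self, fixture_store):
        res = correct_token(fixture_store, tok("stapylococcus"), CorrectionParams())
        assert res.status == "corrected"
        assert res.corrected == "staphylococcus"
        assert res.corrected == res.candidates[0].word

    def test_no_candidates(self, orthogonal_store):
        res = correct_token(orthogonal_store, tok("worda"), CorrectionParams())
        assert res.status == "no_candidate"
        assert res.corrected is None

    def test_oov_without_subword_model_is_skipped(self, orthogonal_store):
        res = correct_token(orthogonal_store, tok("unknownword"), CorrectionParams())
        assert res.status == "skipped_oov"
        assert res.corrected is None


class TestCorrectDocument:
    def test_clean_text_untouched(self, fixture_store, truth_lexicon):
        text = "staphylococcus aureus;\n  streptococcus (2+)."
        # 'aureus' is not in the 16-truth lexicon; extend so nothing is flagged
        lex = Lexicon(terms=truth_lexicon.terms | {"aureus"}, name="x")
        out, results = correct_document(text, lex, fixture_store)
        assert out == text
        assert results == []

    def test_single_injection_repaired_in_place(self, fixture_store, truth_lexicon):
        text = "Culture: Stapylococcus  aureus!"
        lex = Lexicon(terms=truth_lexicon.terms | {"aureus", "culture"}, name="x")
        out, results = correct_document(text, lex, fixture_store)
        assert out == "Culture: Staphylococcus  aureus!"
        assert len(results) == 1 and results[0].status == "corrected"

    def test_non_token_bytes_preserved(self, fixture_store, truth_lexicon):
        text = "x1 #: stapylococcus\t\tperosis -- end"
        lex = Lexicon(terms=truth_lexicon.terms | {"end"}, name="x")
        out, _ = correct_document(text, lex, fixture_store)
        for chunk in ("x1 #: ", "\t\t", " -- end"):
            assert chunk in out

    def test_deterministic(self, fixture_store, truth_lexicon):
        text = "stapylococcus sstreptococcus papatyphi"
        runs = {correct_document(text, truth_lexicon, fixture_store)[0] for _ in range(3)}
        assert len(runs) == 1


class TestGridSearch:
    def test_single_combo_matches_direct_loop(self, fixture_store, profile_pairs):
        table, best = grid_search(
            fixture_store, profile_pairs, {"cos_min": [0.80]}
        )
        assert len(table) == 1
        direct = sum(
            1
            for miss, truth in profile_pairs
            if (r := correct_token(fixture_store, tok(miss), CorrectionParams())).corrected
            == truth
        ) / len(profile_pairs)
        assert table.loc[0, "correction_rate"] == pytest.approx(direct)

    def test_threshold_monotonicity(self, fixture_store, profile_pairs):
        """A stricter cosine threshold can only lose corrections."""
        table, _ = grid_search(fixture_store, profile_pairs, {"cos_min": [0.80, 0.999]})
        loose = table.loc[table.cos_min == 0.80, "correction_rate"].item()
        tight = table.loc[table.cos_min == 0.999, "correction_rate"].item()
        assert tight <= loose

    def test_argmax_agrees_with_enumeration(self, fixture_store, profile_pairs):
        grid = {"top_k": [5, 30], "cos_min": [0.80, 0.95], "dl_max": [1, 3]}
        table, best = grid_search(fixture_store, profile_pairs, grid)
        assert len(table) == 8
        top = table.loc[table.correction_rate.idxmax()]
        assert table.correction_rate.max() == pytest.approx(
            table[
                (table.top_k == best.top_k)
                & (table.cos_min == best.cos_min)
                & (table.dl_max == best.dl_max)
            ].correction_rate.item()
        )

    def test_tightening_shrinks_corrected_set(self, fixture_store, profile_pairs):
        """Corrected types under tighter params are a subset of the looser set."""
        loose = CorrectionParams()
        for tighter in (
            dataclasses.replace(loose, cos_min=0.9),
            dataclasses.replace(loose, dl_max=1),
            dataclasses.replace(loose, top_k=3),
        ):
            loose_set = {
                m
                for m, t in profile_pairs
                if correct_token(fixture_store, tok(m), loose).corrected is not None
            }
            tight_set = {
                m
                for m, t in profile_pairs
                if correct_token(fixture_store, tok(m), tighter).corrected is not None
            }
            assert tight_set <= loose_set
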