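"""Alignment, WER, CNC phoneme, sentence and triplet scoring."""

import itertools
from functools import lru_cache

import edlib
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from asr_audiobench import (
    Alignment,
    align,
    make_cnc_list,
    score_cnc_list,
    score_cnc_word,
    score_sentence,
    score_triplet,
    word_error_rate,
)
from asr_audiobench.scoring import CncScore, extract_digits, normalize_tokens
from asr_audiobench.stimuli import SentenceItem, Triplet, WordItem


def optimal_edit_counts(ref: tuple, hyp: tuple) -> set[tuple[int, int, int]]:
    """Exhaustive oracle: every (S, D, I) achievable by a minimum-cost script."""

    @lru_cache(maxsize=None)
    def all_counts(i: int, j: int) -> set[tuple[int, int, int]]:
        if i == len(ref):
            return {(0, 0, len(hyp) - j)}
        if j == len(hyp):
            return {(0, len(ref) - i, 0)}
        out = set()
        if ref[i] == hyp[j]:
            out |= all_counts(i + 1, j + 1)
        out |= {(s + 1, d, k) for s, d, k in all_counts(i + 1, j + 1)}
        out |= {(s, d + 1, k) for s, d, k in all_counts(i + 1, j)}
        out |= {(s, d, k + 1) for s, d, k in all_counts(i, j + 1)}
        return out

    counts = all_counts(0, 0)
    best = min(s + d + k for s, d, k in counts)
    return {c for c in counts if sum(c) == best}


def token_strings(alphabet, max_len):
    for n in range(max_len + 1):
        yield from itertools.product(alphabet, repeat=n)


class TestAlign:
    def test_identity(self):
        a = align(("a", "b", "c"), ("a", "b", "c"))
        assert (a.substitutions, a.deletions, a.insertions, a.matches) == (0, 0, 0, 3)

    def test_empty_hypothesis_is_all_deletions(self):
        a = align(("a", "b"), ())
        assert a.deletions == 2 and a.matches == 0 and a.wer == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            align((), ("a",))

    def test_counts_are_internally_consistent(self):
        with pytest.raises(ValueError):
            Alignment(substitutions=1, deletions=0, insertions=0, matches=1, ref_length=3)

    def test_exhaustive_oracle_short_sequences(self):
        # every ref/hyp pair up to length 3 over a 3-token alphabet
        alphabet = ("a", "b", "c")
        for ref in token_strings(alphabet, 3):
            if not ref:
                continue
            for hyp in token_strings(alphabet, 3):
                a = align(ref, hyp)
                optimal = optimal_edit_counts(ref, hyp)
                counts = (a.substitutions, a.deletions, a.insertions)
                assert counts in optimal, (ref, hyp, counts, optimal)
                assert a.matches == len(ref) - a.substitutions - a.deletions

    def test_tiebreak_prefers_substitutions_over_del_ins(self):
        # 'ab' -> 'ba' costs 2 either as two substitutions or delete+insert;
        # the documented traceback order must pick the substitutions
        a = align(("a", "b"), ("b", "a"))
        assert (a.substitutions, a.deletions, a.insertions) == (2, 0, 0)

    def test_distance_agrees_with_edlib_on_random_pairs(self):
        rng = np.random.default_rng(0)
        alphabet = "abcde"
        for _ in range(200):
            ref = tuple(rng.choice(list(alphabet), size=rng.integers(1, 30)))
            hyp = tuple(rng.choice(list(alphabet), size=rng.integers(0, 30)))
            expected = edlib.align("".join(ref), "".join(hyp))["editDistance"]
            assert align(ref, hyp).distance == expected

    @given(
        ref=st.lists(st.sampled_from("abc"), min_size=1, max_size=6),
        hyp=st.lists(st.sampled_from("abc"), min_size=1, max_size=6),
    )
    def test_deletion_insertion_symmetry(self, ref, hyp):
        fwd = align(ref, hyp)
        rev = align(hyp, ref)
        assert fwd.distance == rev.distance
        assert fwd.deletions == rev.insertions
        assert fwd.insertions == rev.deletions


class TestWer:
    def test_identical_sequences(self):
        assert word_error_rate(("x", "y"), ("x", "y")) == 0.0

    def test_empty_hypothesis(self):
        assert word_error_rate(("a",) * 4, ()) == 1.0

    def test_one_sub_one_del_one_ins_on_ten_tokens(self):
        ref = tuple(f"w{i}" for i in range(10))
        hyp = list(ref)
        hyp[2] = "sub"         # substitution
        del hyp[7]             # deletion
        hyp.insert(5, "ins")   # insertion at a non-interacting position
        assert word_error_rate(ref, hyp) == pytest.approx(0.3)

    def test_can_exceed_one_with_many_insertions(self):
        assert word_error_rate(("a",), ("a", "x", "y", "z")) == 3.0


class TestCncScoring:
    def test_word_identical(self):
        w = WordItem("bal", ("b", "a", "l"))
        assert score_cnc_word(w, ("b", "a", "l")) == (3, 0)

    def test_word_empty_response(self):
        w = WordItem("bal", ("b", "a", "l"))
        assert score_cnc_word(w, ()) == (0, 0)

    def test_word_with_trailing_insertion(self):
        w = WordItem("bal", ("b", "a", "l"))
        # 3 matches + 1 inserted phoneme; net word contribution 3 - 1 = 2
        assert score_cnc_word(w, ("b", "a", "l", "t")) == (3, 1)

    def test_list_all_correct_is_100_percent(self, cnc_list):
        responses = [w.phonemes for w in cnc_list.words]
        s = score_cnc_list(cnc_list, responses)
        assert s.denominator == 33
        assert s.percent == 100.0

    def test_list_all_empty_is_0_percent(self, cnc_list):
        s = score_cnc_list(cnc_list, [()] * 12)
        assert s.percent == 0.0

    def test_one_word_fully_wrong(self, cnc_list):
        responses = [w.phonemes for w in cnc_list.words]
        responses[5] = ("x9", "y9", "z9")  # symbols outside the inventory
        s = score_cnc_list(cnc_list, responses)
        assert s.phonemes_correct == 30
        assert s.percent == pytest.approx(100 * 30 / 33)

    def test_practice_word_not_scored(self, cnc_list):
        responses = [w.phonemes for w in cnc_list.words]
        responses[0] = ()  # practice response irrelevant
        assert score_cnc_list(cnc_list, responses).percent == 100.0

    def test_insertions_subtracted_with_floor_at_zero(self, cnc_list):
        # 0 correct, many insertions: the percent floors at 0, never negative
        responses = [("q1", "q2", "q3", "q4", "q5")] * 12
        s = score_cnc_list(cnc_list, responses)
        assert s.percent == 0.0
        assert CncScore(phonemes_correct=10, phonemes_inserted=4, denominator=33
                        ).percent == pytest.approx(100 * 6 / 33)

    def test_wrong_response_count_rejected(self, cnc_list):
        with pytest.raises(ValueError):
            score_cnc_list(cnc_list, [()] * 11)

    def test_percent_range_invariant(self, cnc_list):
        rng = np.random.default_rng(4)
        pool = ("b", "a", "l", "t", "k", "oo")
        for _ in range(50):
            responses = [
                tuple(rng.choice(pool, size=rng.integers(0, 6))) for _ in range(12)
            ]
            assert 0.0 <= score_cnc_list(cnc_list, responses).percent <= 100.0


class TestSentenceScoring:
    target = SentenceItem(tokens=("De", "man", "leest", "een", "boek", "in", "huis", "nu"),
                          syllable_count=8)

    def test_verbatim_correct(self):
        assert score_sentence(self.target, self.target.tokens)

    def test_single_substitution_fails_whole_sentence(self):
        resp = list(self.target.tokens)
        resp[1] = "vrouw"
        assert not score_sentence(self.target, resp)

    def test_punctuation_and_case_normalized(self):
        resp = ("de", "MAN", "leest", "een", "boek,", "in", "huis", "nu.")
        assert score_sentence(self.target, resp)

    def test_missing_word_fails(self):
        assert not score_sentence(self.target, self.target.tokens[:-1])

    def test_normalize_drops_pure_punctuation_tokens(self):
        assert normalize_tokens(("Ja!", "—", "nee.")) == ("ja", "nee")


class TestTripletScoring:
    target = Triplet(digits=(1, 2, 5))

    def test_plain_numerals(self):
        assert score_triplet(self.target, ("1", "2", "5"))

    def test_empty_response(self):
        assert not score_triplet(self.target, ())

    def test_unmapped_word_breaks_the_sequence(self):
        # "to" is not a number word: extraction yields (1, 5) != (1, 2, 5)
        assert extract_digits(("one", "to", "five")) == (1, 5)
        assert not score_triplet(self.target, ("one", "to", "five"))

    def test_number_words_dutch_and_english(self):
        assert score_triplet(self.target, ("een", "twee", "vijf"))
        assert score_triplet(self.target, ("one", "two", "five"))

    def test_digit_run_token(self):
        # apps often render "125" as one token
        assert score_triplet(self.target, ("125",))

    def test_sentence_construction_around_digits(self):
        # surrounding non-digit words are dropped by extraction
        assert score_triplet(self.target, ("ik", "hoor", "1", "2", "5", "nu"))

    def test_extra_digit_fails(self):
        assert not score_triplet(self.target, ("1", "2", "5", "9"))
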