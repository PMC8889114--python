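"""Correctness metrics for transcriber responses.

Four clinical scoring rules, each applied to token sequences produced by a
transcriber (real or simulated):

* token **alignment** and **word error rate** (WER) — minimum-edit-cost
  alignment with unit substitution/deletion/insertion costs;
  WER = (S + D + I) / reference length, the ASR-field convention;
* **CNC phoneme scoring** — per-word phoneme matches from the same alignment,
  aggregated over the 11 scored words of a 12-word list, with inserted
  phonemes subtracted from the score (clinical rule) and the percentage
  floored at 0;
* **whole-sentence scoring** — a sentence is correct only when the normalized
  response equals the normalized target exactly (Plomp-test rule);
* **triplet scoring** — digit tokens are extracted from the response (apps
  tend to emit running sentences rather than isolated numbers, so numerals and
  configured number-words are mapped to digits and everything else is
  dropped); the triplet is correct iff the extracted digit sequence equals the
  target's three digits in order.

Among equal-cost alignments the traceback deterministically prefers
match > substitution > deletion > insertion, so all reported counts are
reproducible.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stimuli import CncList, SentenceItem, Triplet, WordItem

__all__ = [
    "Alignment",
    "CncScore",
    "align",
    "word_error_rate",
    "score_cnc_word",
    "score_cnc_list",
    "score_sentence",
    "score_triplet",
    "normalize_tokens",
    "extract_digits",
    "NUMBER_WORDS_EN",
    "NUMBER_WORDS_NL",
    "DEFAULT_NUMBER_WORDS",
]


@dataclass(frozen=True)
class Alignment:
    """Edit-operation counts of a minimum-cost alignment."""

    substitutions: int
    deletions: int
    insertions: int
    matches: int
    ref_length: int

    def __post_init__(self) -> None:
        if min(self.substitutions, self.deletions, self.insertions, self.matches) < 0:
            raise ValueError("alignment counts must be non-negative")
        if self.matches + self.substitutions + self.deletions != self.ref_length:
            raise ValueError(
                "matches + substitutions + deletions must equal ref_length "
                f"({self.matches}+{self.substitutions}+{self.deletions} != {self.ref_length})"
            )

    @property
    def distance(self) -> int:
        """Levenshtein distance: S + D + I."""
        return self.substitutions + self.deletions + self.insertions

    @property
    def wer(self) -> float:
        return self.distance / self.ref_length


def _edit_matrix(ref_ids: np.ndarray, hyp_ids: np.ndarray) -> np.ndarray:
    """Full unit-cost edit-distance matrix, rows = ref prefix, cols = hyp prefix."""
    n, m = len(ref_ids), len(hyp_ids)
    cost = np.empty((n + 1, m + 1), dtype=np.int32)
    cost[0, :] = np.arange(m + 1)
    ar = np.arange(m + 1)
    for i in range(1, n + 1):
        prev = cost[i - 1]
        cand = np.empty(m + 1, dtype=np.int32)
        cand[0] = i
        # best way to reach column j without using an insertion as last step
        cand[1:] = np.minimum(prev[:-1] + (hyp_ids != ref_ids[i - 1]), prev[1:] + 1)
        # fold in insertion chains via a running minimum of cand[j] - j
        cost[i] = np.minimum.accumulate(cand - ar) + ar
    return cost


def align(ref: Sequence[str], hyp: Sequence[str]) -> Alignment:
    """Minimum-edit-cost alignment counts between reference and hypothesis.

    Unit costs; S + D + I equals the Levenshtein distance. ``ref`` must be
    non-empty (WER is undefined for an empty reference); ``hyp`` may be empty.
    """
    ref = tuple(ref)
    hyp = tuple(hyp)
    if not ref:
        raise ValueError("reference must be non-empty (WER undefined)")
    ids = {tok: i for i, tok in enumerate(dict.fromkeys(ref + hyp))}
    ref_ids = np.array([ids[t] for t in ref], dtype=np.int64)
    hyp_ids = np.array([ids[t] for t in hyp], dtype=np.int64)
    cost = _edit_matrix(ref_ids, hyp_ids)

    # traceback; tie-break: match > substitution > deletion > insertion
    i, j = len(ref), len(hyp)
    n_sub = n_del = n_ins = n_match = 0
    while i > 0 or j > 0:
        c = cost[i, j]
        if i > 0 and j > 0 and ref[i - 1] == hyp[j - 1] and c == cost[i - 1, j - 1]:
            n_match += 1
            i, j = i - 1, j - 1
        elif i > 0 and j > 0 and ref[i - 1] != hyp[j - 1] and c == cost[i - 1, j - 1] + 1:
            n_sub += 1
            i, j = i - 1, j - 1
        elif i > 0 and c == cost[i - 1, j] + 1:
            n_del += 1
            i -= 1
        else:
            n_ins += 1
            j -= 1
    return Alignment(
        substitutions=n_sub,
        deletions=n_del,
        insertions=n_ins,
        matches=n_match,
        ref_length=len(ref),
    )


def word_error_rate(ref: Sequence[str], hyp: Sequence[str]) -> float:
    """WER = (substitutions + deletions + insertions) / reference length.

    May exceed 1 when the hypothesis carries many insertions.
    """
    return align(ref, hyp).wer


# ---------------------------------------------------------------------------
# CNC phoneme scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CncScore:
    """Aggregate phoneme recognition score of one CNC list.

    ``percent = 100 * max(0, phonemes_correct - phonemes_inserted) / denominator``;
    the denominator of a standard list is 3 phonemes x 11 scored words = 33.
    """

    phonemes_correct: int
    phonemes_inserted: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if self.phonemes_correct < 0 or self.phonemes_inserted < 0:
            raise ValueError("counts must be non-negative")

    @property
    def percent(self) -> float:
        net = max(0, self.phonemes_correct - self.phonemes_inserted)
        return 100.0 * net / self.denominator


def score_cnc_word(target: WordItem, response: Sequence[str]) -> tuple[int, int]:
    """(correct phonemes, inserted phonemes) for one word via alignment.

    The response is the word's *final* displayed phoneme decomposition; an
    empty response scores (0, 0).
    """
    response = tuple(response)
    if not response:
        return 0, 0
    a = align(target.phonemes, response)
    return a.matches, a.insertions


def score_cnc_list(cnc_list: CncList, responses: Sequence[Sequence[str]]) -> CncScore:
    """Phoneme score over the 11 scored words of a 12-word list.

    ``responses`` holds one phoneme sequence per presented word, in order,
    including the (unscored, possibly empty) practice response.
    """
    responses = [tuple(r) for r in responses]
    if len(responses) != len(cnc_list.words):
        raise ValueError(
            f"expected {len(cnc_list.words)} responses (practice included), "
            f"got {len(responses)}"
        )
    correct = inserted = 0
    for word, resp in zip(cnc_list.scored_words, responses[1:]):
        c, ins = score_cnc_word(word, resp)
        correct += c
        inserted += ins
    return CncScore(
        phonemes_correct=correct,
        phonemes_inserted=inserted,
        denominator=cnc_list.scored_phoneme_count,
    )


# ---------------------------------------------------------------------------
# Sentence and triplet scoring
# ---------------------------------------------------------------------------

_PUNCT_TABLE = str.maketrans("", "", string.punctuation + "…‘’“”—–¿¡")


def normalize_tokens(tokens: Iterable[str]) -> tuple[str, ...]:
    """Casefold and strip punctuation characters; drop tokens left empty."""
    out = []
    for tok in tokens:
        t = tok.casefold().translate(_PUNCT_TABLE)
        if t:
            out.append(t)
    return tuple(out)


def score_sentence(target: SentenceItem, response: Sequence[str]) -> bool:
    """All-or-nothing sentence scoring: correct iff the whole sentence matches.

    Normalization (casefold, punctuation strip) is applied to both sides; any
    substituted, missing or extra word makes the sentence incorrect.
    """
    return normalize_tokens(target.tokens) == normalize_tokens(response)


NUMBER_WORDS_EN: Mapping[str, int] = {
    "zero": 0, "oh": 0, "one": 1, "two": 2, "three": 3, "four": 4,
    "five": 5, "six": 6, "seven": 7, "eight": 8, "nine": 9,
}
NUMBER_WORDS_NL: Mapping[str, int] = {
    "nul": 0, "een": 1, "één": 1, "twee": 2, "drie": 3, "vier": 4,
    "vijf": 5, "zes": 6, "zeven": 7, "acht": 8, "negen": 9,
}
DEFAULT_NUMBER_WORDS: Mapping[str, int] = {**NUMBER_WORDS_EN, **NUMBER_WORDS_NL}


def extract_digits(
    tokens: Sequence[str],
    number_words: Mapping[str, int] = DEFAULT_NUMBER_WORDS,
) -> tuple[int, ...]:
    """Digits heard in a free-text response, in order.

    Numeral tokens contribute their digits (a run like "125" contributes
    1, 2, 5); configured number-words map to single digits; all other tokens
    are dropped.
    """
    digits: list[int] = []
    for tok in normalize_tokens(tokens):
        if tok.isdigit():
            digits.extend(int(ch) for ch in tok)
        elif tok in number_words:
            digits.append(number_words[tok])
    return tuple(digits)


def score_triplet(
    target: Triplet,
    response: Sequence[str],
    number_words: Mapping[str, int] = DEFAULT_NUMBER_WORDS,
) -> bool:
    """Triplet correct iff the extracted digit sequence equals the target."""
    return extract_digits(response, number_words) == target.digits
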