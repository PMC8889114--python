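"""Speech-test stimulus material.

Clinical speech audiometry uses three stimulus classes, all emulated here with
the structural properties of the Dutch clinical materials:

* **CNC word lists** — lists of twelve monosyllabic words with a
  consonant-nucleus-consonant phoneme structure. The first word is a practice
  item and is excluded from scoring, so a standard list is scored over
  11 words x 3 phonemes = 33 phonemes.
* **Digit triplets** — series of three-digit sequences (e.g. "1 2 5") used by
  the digits-in-noise (DIN) test; a clinical series holds 24 triplets.
* **Sentence lists** — 13 sentences of 8–9 syllables each, used by the
  adaptive sentences-in-noise (Plomp) procedure.

A fourth class, free-running **dialogues**, provides reference transcripts for
word-error-rate evaluation.

Phonemes are opaque tokens carried by the stimulus file: no grapheme-to-phoneme
conversion is performed, and phoneme segmentation (diphthongs, clusters) is a
property of the input material, exactly as on a clinical list. Phonetic
balancing of the clinical lists is deliberately not emulated — words are drawn
uniformly without replacement — because balancing constraints are irrelevant to
the scoring and staircase machinery this package exercises.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhonemeInventory",
    "WordItem",
    "CncList",
    "Triplet",
    "SentenceItem",
    "Dialogue",
    "DEFAULT_INVENTORY",
    "DEFAULT_LEXICON",
    "InvalidInventoryError",
    "InvalidLexiconError",
    "StimulusParseError",
    "make_cnc_list",
    "make_triplet_series",
    "make_sentence_list",
    "make_dialogue",
    "read_stimuli",
    "write_stimuli",
]

CNC_LIST_LENGTH = 12
SCORED_WORDS_PER_LIST = CNC_LIST_LENGTH - 1
PHONEMES_PER_CNC_WORD = 3
SENTENCES_PER_PLOMP_LIST = 13
SENTENCE_SYLLABLES = (8, 9)


class InvalidInventoryError(ValueError):
    """Phoneme inventory cannot produce the requested stimuli."""


class InvalidLexiconError(ValueError):
    """Sentence lexicon cannot reach the required syllable count."""


class StimulusParseError(ValueError):
    """A stimulus file violates its documented format."""


@dataclass(frozen=True)
class PhonemeInventory:
    """Consonant (C) and nucleus (N) token inventories.

    Tokens are opaque short strings; each symbol belongs to exactly one of the
    two classes.
    """

    consonants: tuple[str, ...]
    nuclei: tuple[str, ...]

    def __post_init__(self) -> None:
        if not all(self.consonants) or not all(self.nuclei):
            raise InvalidInventoryError("phoneme symbols must be non-empty")
        if set(self.consonants) & set(self.nuclei):
            raise InvalidInventoryError(
                "a symbol may not be both a consonant and a nucleus: "
                f"{sorted(set(self.consonants) & set(self.nuclei))}"
            )

    @property
    def n_cnc_words(self) -> int:
        """Number of distinct C-N-C words this inventory spans."""
        return len(self.consonants) ** 2 * len(self.nuclei)


#: Compact Dutch-flavoured inventory; symbols are illustrative, not a claim of
#: phonological completeness (see module docstring).
DEFAULT_INVENTORY = PhonemeInventory(
    consonants=("b", "d", "f", "g", "h", "j", "k", "l", "m", "n", "p", "r", "s", "t", "v", "z"),
    nuclei=("a", "aa", "e", "ee", "i", "ie", "o", "oo", "u", "uu", "ei", "ui", "ou", "oe"),
)


@dataclass(frozen=True)
class WordItem:
    """A word stimulus: orthography plus its ordered phoneme decomposition."""

    orthography: str
    phonemes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.orthography:
            raise ValueError("orthography must be non-empty")
        if not self.phonemes or not all(self.phonemes):
            raise ValueError("phonemes must be a non-empty sequence of non-empty tokens")
        object.__setattr__(self, "phonemes", tuple(self.phonemes))


@dataclass(frozen=True)
class CncList:
    """A 12-word CNC list; the first word is the unscored practice item."""

    list_id: str
    words: tuple[WordItem, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "words", tuple(self.words))
        if len(self.words) != CNC_LIST_LENGTH:
            raise ValueError(
                f"a CNC list holds exactly {CNC_LIST_LENGTH} words, got {len(self.words)}"
            )
        for w in self.words:
            if len(w.phonemes) != PHONEMES_PER_CNC_WORD:
                raise ValueError(
                    f"CNC word {w.orthography!r} must have exactly "
                    f"{PHONEMES_PER_CNC_WORD} phonemes (C-N-C), got {len(w.phonemes)}"
                )

    @property
    def practice_word(self) -> WordItem:
        return self.words[0]

    @property
    def scored_words(self) -> tuple[WordItem, ...]:
        """Words 2–12: the 11 words that enter the phoneme score."""
        return self.words[1:]

    @property
    def scored_phoneme_count(self) -> int:
        """Denominator of the phoneme recognition score (33 for a standard list)."""
        return sum(len(w.phonemes) for w in self.scored_words)


@dataclass(frozen=True)
class Triplet:
    """An ordered digit triplet, each digit in 0–9."""

    digits: tuple[int, int, int]

    def __post_init__(self) -> None:
        digits = tuple(int(d) for d in self.digits)
        if len(digits) != 3:
            raise ValueError(f"a triplet holds exactly 3 digits, got {len(digits)}")
        if not all(0 <= d <= 9 for d in digits):
            raise ValueError(f"digits must be in 0–9, got {digits}")
        object.__setattr__(self, "digits", digits)

    @property
    def tokens(self) -> tuple[str, str, str]:
        """The triplet as presentation tokens ("1", "2", "5")."""
        return tuple(str(d) for d in self.digits)  # type: ignore[return-value]


@dataclass(frozen=True)
class SentenceItem:
    """A sentence stimulus with its syllable count (8 or 9)."""

    tokens: tuple[str, ...]
    syllable_count: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if not self.tokens:
            raise ValueError("a sentence must contain at least one token")
        if self.syllable_count not in SENTENCE_SYLLABLES:
            raise ValueError(
                f"sentence syllable count must be in {SENTENCE_SYLLABLES}, "
                f"got {self.syllable_count}"
            )

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


@dataclass(frozen=True)
class Dialogue:
    """A reference transcript for free-running dialogue transcription."""

    tokens: tuple[str, ...]
    language_tag: str = "nl"

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if not self.tokens:
            raise ValueError("a dialogue must contain at least one token")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_cnc_list(
    seed: int,
    inventory: PhonemeInventory = DEFAULT_INVENTORY,
    list_id: str | None = None,
) -> CncList:
    """Draw a 12-word CNC list uniformly without replacement.

    Every word follows the C-N-C pattern; words are distinct within the list;
    orthography is the concatenation of the phoneme symbols. Deterministic for
    a given (seed, inventory).
    """
    if len(inventory.consonants) < 2 or len(inventory.nuclei) < 2:
        raise InvalidInventoryError("need at least 2 consonants and 2 nuclei")
    if inventory.n_cnc_words < CNC_LIST_LENGTH:
        raise InvalidInventoryError(
            f"inventory spans only {inventory.n_cnc_words} distinct C-N-C words; "
            f"{CNC_LIST_LENGTH} are needed"
        )
    rng = np.random.default_rng(seed)
    n_c, n_n = len(inventory.consonants), len(inventory.nuclei)
    flat = rng.choice(inventory.n_cnc_words, size=CNC_LIST_LENGTH, replace=False)
    words = []
    for idx in flat:
        c1, rest = divmod(int(idx), n_n * n_c)
        n, c2 = divmod(rest, n_c)
        phonemes = (inventory.consonants[c1], inventory.nuclei[n], inventory.consonants[c2])
        words.append(WordItem(orthography="".join(phonemes), phonemes=phonemes))
    return CncList(list_id=list_id or f"cnc-{seed}", words=tuple(words))


def make_triplet_series(seed: int, n: int = 24) -> tuple[Triplet, ...]:
    """Draw ``n`` digit triplets with digits i.i.d. uniform over 0–9."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 10, size=(n, 3))
    return tuple(Triplet(digits=tuple(row)) for row in draws.tolist())


#: Small synthetic Dutch-like lexicon (word -> syllable count) for sentence
#: generation; real clinical sentence lists carry their own material.
DEFAULT_LEXICON: Mapping[str, int] = {
    "de": 1, "het": 1, "een": 1, "man": 1, "vrouw": 1, "kind": 1, "huis": 1,
    "boek": 1, "gaat": 1, "komt": 1, "ziet": 1, "leest": 1, "loopt": 1,
    "naar": 1, "straat": 1, "vandaag": 2, "morgen": 2, "buiten": 2,
    "lopen": 2, "spelen": 2, "kinderen": 3, "gisteren": 3,
}


def make_sentence_list(
    seed: int,
    lexicon: Mapping[str, int] = DEFAULT_LEXICON,
    n_sentences: int = SENTENCES_PER_PLOMP_LIST,
) -> tuple[SentenceItem, ...]:
    """Build ``n_sentences`` sentences summing to 8 or 9 syllables each.

    Words are drawn uniformly from the lexicon, restricted at each step to
    words that still fit the target syllable count; deterministic per seed.
    """
    if not lexicon:
        raise InvalidLexiconError("lexicon is empty")
    for word, syl in lexicon.items():
        if syl < 1:
            raise InvalidLexiconError(f"word {word!r} has syllable count {syl} < 1")
    counts = sorted(set(lexicon.values()))
    if min(counts) > max(SENTENCE_SYLLABLES):
        raise InvalidLexiconError(
            "lexicon cannot reach 8–9 syllables: every word exceeds 9 syllables"
        )
    if not _reachable_targets(counts):
        raise InvalidLexiconError(
            f"no combination of syllable counts {counts} sums to 8 or 9"
        )
    words = sorted(lexicon)
    rng = np.random.default_rng(seed)
    sentences = []
    for _ in range(n_sentences):
        for _attempt in range(1000):
            target = int(rng.choice(SENTENCE_SYLLABLES))
            tokens: list[str] = []
            total = 0
            while total < target:
                fits = [w for w in words if lexicon[w] <= target - total]
                if not fits:
                    break
                w = fits[int(rng.integers(len(fits)))]
                tokens.append(w)
                total += lexicon[w]
            if total == target:
                sentences.append(SentenceItem(tokens=tuple(tokens), syllable_count=total))
                break
        else:  # pragma: no cover - guarded by reachability check
            raise InvalidLexiconError("could not assemble an 8–9 syllable sentence")
    return tuple(sentences)


def _reachable_targets(counts: Sequence[int]) -> bool:
    """True if some multiset of ``counts`` sums exactly to 8 or 9."""
    reachable = {0}
    for s in range(1, max(SENTENCE_SYLLABLES) + 1):
        if any(s - c in reachable for c in counts if s - c >= 0):
            reachable.add(s)
    return any(t in reachable for t in SENTENCE_SYLLABLES)


def make_dialogue(
    seed: int,
    n_words: int = 256,
    language_tag: str = "nl",
    vocabulary: Sequence[str] | None = None,
) -> Dialogue:
    """Draw a synthetic dialogue transcript of ``n_words`` tokens.

    Defaults emulate the length of the Dutch reference dialogue (256 words);
    use ``n_words=248`` for the English analogue.
    """
    if n_words < 1:
        raise ValueError(f"n_words must be >= 1, got {n_words}")
    vocab = tuple(vocabulary) if vocabulary is not None else tuple(sorted(DEFAULT_LEXICON))
    if not vocab:
        raise ValueError("vocabulary must be non-empty")
    rng = np.random.default_rng(seed)
    tokens = tuple(vocab[i] for i in rng.integers(len(vocab), size=n_words))
    return Dialogue(tokens=tokens, language_tag=language_tag)


# ---------------------------------------------------------------------------
# File I/O (UTF-8 CSV; dialogues as token-normalized text lines)
# ---------------------------------------------------------------------------

_KINDS = ("cnc", "triplets", "sentences", "dialogue")


def write_stimuli(collection, path: str | Path, kind: str) -> None:
    """Serialize a stimulus collection to its documented on-disk format.

    Formats (all UTF-8):

    * ``cnc`` — CSV with columns ``list_id, position (1–12), orthography,
      phonemes`` (pipe-separated). Accepts one :class:`CncList` or a sequence.
    * ``triplets`` — CSV with columns ``series_id, position, d1, d2, d3``.
    * ``sentences`` — CSV with columns ``list_id, position, text, syllables``.
    * ``dialogue`` — one token-normalized utterance per line, first line a
      ``# lang=<tag>`` header.
    """
    path = Path(path)
    if kind == "cnc":
        lists = [collection] if isinstance(collection, CncList) else list(collection)
        rows = [
            {
                "list_id": cl.list_id,
                "position": i + 1,
                "orthography": w.orthography,
                "phonemes": "|".join(w.phonemes),
            }
            for cl in lists
            for i, w in enumerate(cl.words)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif kind == "triplets":
        rows = [
            {"series_id": "s1", "position": i + 1,
             "d1": t.digits[0], "d2": t.digits[1], "d3": t.digits[2]}
            for i, t in enumerate(collection)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif kind == "sentences":
        rows = [
            {"list_id": "l1", "position": i + 1, "text": s.text,
             "syllables": s.syllable_count}
            for i, s in enumerate(collection)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif kind == "dialogue":
        d: Dialogue = collection
        lines = [f"# lang={d.language_tag}"]
        # one utterance per line, 12 tokens max, mirrors turn-taking transcripts
        for i in range(0, len(d.tokens), 12):
            lines.append(" ".join(d.tokens[i : i + 12]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}; expected one of {_KINDS}")


def read_stimuli(path: str | Path, kind: str):
    """Parse a stimulus file written by :func:`write_stimuli`.

    Raises :class:`StimulusParseError` naming the offending line/field on any
    structural violation (wrong list length, non-CNC word, bad digit, ...).
    """
    path = Path(path)
    if kind == "cnc":
        df = _read_csv(path, {"list_id", "position", "orthography", "phonemes"})
        lists = []
        for list_id, group in df.groupby("list_id", sort=False):
            group = group.sort_values("position")
            if list(group["position"]) != list(range(1, CNC_LIST_LENGTH + 1)):
                raise StimulusParseError(
                    f"{path}: list {list_id!r} does not hold positions 1–{CNC_LIST_LENGTH} "
                    f"(got {len(group)} rows)"
                )
            words = []
            for row in group.itertuples():
                phonemes = tuple(str(row.phonemes).split("|"))
                try:
                    words.append(WordItem(orthography=str(row.orthography), phonemes=phonemes))
                except ValueError as exc:
                    raise StimulusParseError(
                        f"{path}: list {list_id!r} position {row.position}: {exc}"
                    ) from exc
            try:
                lists.append(CncList(list_id=str(list_id), words=tuple(words)))
            except ValueError as exc:
                raise StimulusParseError(f"{path}: list {list_id!r}: {exc}") from exc
        return tuple(lists)
    if kind == "triplets":
        df = _read_csv(path, {"series_id", "position", "d1", "d2", "d3"})
        out = []
        for row in df.sort_values("position").itertuples():
            try:
                out.append(Triplet(digits=(int(row.d1), int(row.d2), int(row.d3))))
            except ValueError as exc:
                raise StimulusParseError(f"{path}: position {row.position}: {exc}") from exc
        return tuple(out)
    if kind == "sentences":
        df = _read_csv(path, {"list_id", "position", "text", "syllables"})
        out = []
        for row in df.sort_values("position").itertuples():
            try:
                out.append(
                    SentenceItem(tokens=tuple(str(row.text).split()),
                                 syllable_count=int(row.syllables))
                )
            except ValueError as exc:
                raise StimulusParseError(f"{path}: position {row.position}: {exc}") from exc
        return tuple(out)
    if kind == "dialogue":
        lines = path.read_text(encoding="utf-8").splitlines()
        lang = "nl"
        tokens: list[str] = []
        for i, line in enumerate(lines, start=1):
            if line.startswith("#"):
                if "lang=" in line:
                    lang = line.split("lang=", 1)[1].strip()
                continue
            tokens.extend(line.split())
        if not tokens:
            raise StimulusParseError(f"{path}: dialogue contains no tokens")
        return Dialogue(tokens=tuple(tokens), language_tag=lang)
    raise ValueError(f"unknown stimulus kind {kind!r}; expected one of {_KINDS}")


def _read_csv(path: Path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise StimulusParseError(f"{path}: not parseable as CSV: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise StimulusParseError(f"{path}: missing required columns {sorted(missing)}")
    return df
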