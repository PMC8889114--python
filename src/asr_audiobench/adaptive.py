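"""Adaptive and fixed-level speech-reception test procedures.

Two adaptive speech-reception-threshold (SRT) procedures plus a fixed-level
battery, all driven by any *responder* — a callable
``responder(stimulus_tokens, AcousticCondition) -> response_tokens`` — so the
same machinery runs against the parametric simulator, a deterministic
threshold observer, or (in principle) logged responses from a real app.

Digits-in-noise (DIN)
    1-up/1-down staircase over SNR. Defaults follow the clinical protocol:
    noise fixed at 60 dB SPL, first triplet at +6 dB SNR, 2 dB steps, a series
    of 24 triplets whose first 4 are discarded. The SRT estimate is the mean
    of the SNRs of the retained trials plus, by the standard convention, the
    SNR that would have been presented next ("virtual" trial).

Sentences-in-noise / in-quiet (Plomp procedure)
    A 13-sentence list with all-or-nothing sentence scoring. Sentence 1 is
    re-presented at levels ascending in 4 dB steps until it is reproduced
    correctly; sentences 2–13 then follow a 1-up/1-down rule with 2 dB steps.
    The SRT is the mean of the presentation levels of sentences 5–13 plus the
    virtual 14th level. With ``quiet_mode`` the track runs on absolute
    presentation level instead of SNR, yielding the SRT in quiet.

Fixed levels (speech audiogram)
    CNC lists presented at a grid of levels in quiet (clinically 45–85 dB
    SPL), each scored as percent phonemes correct, yielding the points of the
    speech audiogram.

The 1-up/1-down rule converges on the 50% point of the *item-level*
psychometric function (triplet or whole sentence), which is exactly how the
clinical SRT is defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .scoring import CncScore, score_cnc_list, score_sentence, score_triplet
from .stimuli import CncList, SentenceItem, Triplet
from .transcriber import AcousticCondition

__all__ = [
    "Responder",
    "StaircaseConfig",
    "PlompConfig",
    "Trial",
    "SrtResult",
    "AudiogramPoint",
    "run_din",
    "run_plomp",
    "run_fixed_levels",
]

Responder = Callable[[Sequence[str], AcousticCondition], Sequence[str]]


@dataclass(frozen=True)
class StaircaseConfig:
    """DIN staircase parameters (defaults = clinical protocol)."""

    noise_level: float = 60.0
    initial_snr: float = 6.0
    step: float = 2.0
    n_trials: int = 24
    n_discard: int = 4
    include_virtual_trial: bool = True

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if not 0 <= self.n_discard < self.n_trials:
            raise ValueError(
                f"need 0 <= n_discard < n_trials, got {self.n_discard} / {self.n_trials}"
            )


@dataclass(frozen=True)
class PlompConfig:
    """Plomp sentence-procedure parameters (defaults = published procedure)."""

    n_sentences: int = 13
    step: float = 2.0
    first_sentence_step: float = 4.0
    start_snr_or_level: float = -10.0
    averaging_start: int = 5
    quiet_mode: bool = False
    noise_level: float = 70.0
    max_first_sentence_presentations: int = 100

    def __post_init__(self) -> None:
        if self.step <= 0 or self.first_sentence_step <= 0:
            raise ValueError("steps must be > 0")
        if not 1 <= self.averaging_start <= self.n_sentences:
            raise ValueError(
                f"averaging_start must be in 1..{self.n_sentences}, "
                f"got {self.averaging_start}"
            )


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation and its outcome."""

    index: int
    stimulus_ref: str
    snr_or_level: float
    response_tokens: tuple[str, ...]
    correct: bool

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("trial index starts at 1")
        object.__setattr__(self, "response_tokens", tuple(self.response_tokens))


@dataclass(frozen=True)
class SrtResult:
    """Outcome of one adaptive run.

    ``srt`` is the mean of ``averaged_levels`` (which include the virtual
    next level when the config asks for it); ``sd_within_run`` is their
    sample standard deviation — the within-run spread reported as error bars
    on clinical SRT plots.
    """

    srt: float
    trials: tuple[Trial, ...]
    averaged_levels: tuple[float, ...]
    virtual_level: float | None
    sd_within_run: float


def _finish(trials: list[Trial], averaged: list[float], virtual: float | None) -> SrtResult:
    levels = list(averaged) + ([virtual] if virtual is not None else [])
    arr = np.asarray(levels, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return SrtResult(
        srt=float(arr.mean()),
        trials=tuple(trials),
        averaged_levels=tuple(levels),
        virtual_level=virtual,
        sd_within_run=sd,
    )


def run_din(
    responder: Responder,
    triplets: Sequence[Triplet],
    cfg: StaircaseConfig = StaircaseConfig(),
) -> SrtResult:
    """Run one DIN series through ``responder`` and estimate the SRT.

    Triplets are consumed in order without replacement; at least
    ``cfg.n_trials`` must be supplied. After a correct triplet the SNR drops
    by ``cfg.step``; after an incorrect one it rises by ``cfg.step``.
    """
    triplets = tuple(triplets)
    if len(triplets) < cfg.n_trials:
        raise ValueError(
            f"need at least {cfg.n_trials} triplets, got {len(triplets)}"
        )
    snr = float(cfg.initial_snr)
    trials: list[Trial] = []
    presented: list[float] = []
    for k in range(cfg.n_trials):
        triplet = triplets[k]
        cond = AcousticCondition(level=cfg.noise_level + snr, snr=snr, rt=0.0)
        response = tuple(responder(triplet.tokens, cond))
        correct = score_triplet(triplet, response)
        trials.append(
            Trial(
                index=k + 1,
                stimulus_ref="-".join(triplet.tokens),
                snr_or_level=snr,
                response_tokens=response,
                correct=correct,
            )
        )
        presented.append(snr)
        snr += -cfg.step if correct else cfg.step
    averaged = presented[cfg.n_discard :]
    virtual = snr if cfg.include_virtual_trial else None
    return _finish(trials, averaged, virtual)


def run_plomp(
    responder: Responder,
    sentences: Sequence[SentenceItem],
    cfg: PlompConfig = PlompConfig(),
) -> SrtResult:
    """Run the Plomp sentence procedure and estimate the SRT.

    ``cfg.quiet_mode`` selects whether the track variable is an absolute
    presentation level (SRT in quiet) or an SNR over a fixed masker
    (SRT in noise).
    """
    sentences = tuple(sentences)
    if len(sentences) != cfg.n_sentences:
        raise ValueError(
            f"expected exactly {cfg.n_sentences} sentences, got {len(sentences)}"
        )

    def present(x: float, sentence: SentenceItem) -> tuple[tuple[str, ...], bool]:
        if cfg.quiet_mode:
            cond = AcousticCondition(level=x, snr=None, rt=0.0)
        else:
            cond = AcousticCondition(level=cfg.noise_level + x, snr=x, rt=0.0)
        response = tuple(responder(sentence.tokens, cond))
        return response, score_sentence(sentence, response)

    trials: list[Trial] = []
    x = float(cfg.start_snr_or_level)
    idx = 0

    # sentence 1: ascending search in first_sentence_step increments
    first = sentences[0]
    for _ in range(cfg.max_first_sentence_presentations):
        idx += 1
        response, correct = present(x, first)
        trials.append(
            Trial(index=idx, stimulus_ref="s1", snr_or_level=x,
                  response_tokens=response, correct=correct)
        )
        if correct:
            break
        x += cfg.first_sentence_step
    else:
        raise RuntimeError(
            "first sentence never reproduced correctly within "
            f"{cfg.max_first_sentence_presentations} ascending presentations"
        )
    sentence_levels = [x]  # level at which each sentence was (finally) presented
    x -= cfg.step

    # sentences 2..n: 1-up/1-down
    for sentence_no in range(2, cfg.n_sentences + 1):
        idx += 1
        response, correct = present(x, sentences[sentence_no - 1])
        trials.append(
            Trial(index=idx, stimulus_ref=f"s{sentence_no}", snr_or_level=x,
                  response_tokens=response, correct=correct)
        )
        sentence_levels.append(x)
        x += -cfg.step if correct else cfg.step

    averaged = sentence_levels[cfg.averaging_start - 1 :]
    return _finish(trials, averaged, virtual=x)


@dataclass(frozen=True)
class AudiogramPoint:
    """One point of the speech audiogram: level vs phoneme score."""

    level: float
    score: CncScore

    @property
    def percent(self) -> float:
        return self.score.percent


def run_fixed_levels(
    responder: Responder,
    lists: Sequence[CncList],
    levels: Sequence[float] = (45.0, 55.0, 65.0, 75.0, 85.0),
) -> tuple[AudiogramPoint, ...]:
    """Present one CNC list per level in quiet and score phonemes correct.

    If fewer lists than levels are supplied the lists are reused cyclically
    (with a warning), mirroring — imperfectly — clinical reuse of material.
    """
    levels = tuple(float(x) for x in levels)
    lists = tuple(lists)
    if not levels:
        raise ValueError("levels must be non-empty")
    if not lists:
        raise ValueError("at least one CNC list is required")
    if len(lists) < len(levels):
        warnings.warn(
            f"{len(levels)} levels but only {len(lists)} lists: lists will be reused",
            stacklevel=2,
        )
    points = []
    for i, level in enumerate(levels):
        cnc = lists[i % len(lists)]
        cond = AcousticCondition(level=level, snr=None, rt=0.0)
        responses = [tuple(responder(w.phonemes, cond)) for w in cnc.words]
        points.append(AudiogramPoint(level=level, score=score_cnc_list(cnc, responses)))
    return tuple(points)
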