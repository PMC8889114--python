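"""Parametric simulated speech transcriber.

The simulator stands in for a real speech-to-text app in the test battery. Its
latent performance is a psychometric function: each stimulus token is
transcribed correctly with probability

    p(x) = p_floor + (1 - p_floor) * logistic((x - midpoint) / s)

where the drive ``x`` is the presentation level in dB SPL (quiet condition) or
the effective signal-to-noise ratio in dB (noise condition), and
``s = 25 / slope`` converts the slope at the midpoint, expressed in %/dB on the
0–100% curve, into the logistic scale. Reverberation degrades the effective
SNR linearly: ``x = snr - rt_penalty * rt`` — a minimal monotone model of the
reverberation axis; no room acoustics are simulated.

Incorrect tokens become substitutions (a different token drawn from the
model's vocabulary) or deletions, per the configured error mix; insertions
arrive as an independent Poisson process at ``insertion_rate`` expected
insertions per stimulus token. Token errors are independent across positions.

Determinism: every :meth:`TranscriberModel.transcribe` call is reproducible
from ``(model.seed, call_key)``. The three randomness sources (per-token
correctness, error type/identity, insertions) use separate substreams, so two
conditions replayed with the same call key share the same per-token luck —
common random numbers — which makes condition comparisons (e.g. WER grids)
variance-free along the accuracy axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "AcousticCondition",
    "TranscriberModel",
    "LogisticItemResponder",
    "ThresholdResponder",
    "PerfectResponder",
    "SilentResponder",
    "slope_to_scale",
]


def slope_to_scale(slope_pct_per_db: float) -> float:
    """Logistic scale parameter s (dB) from midpoint slope in %/dB.

    d/dx [100 * logistic(x/s)] at 0 equals 25/s %/dB.
    """
    if slope_pct_per_db <= 0:
        raise ValueError(f"slope must be > 0, got {slope_pct_per_db}")
    return 25.0 / slope_pct_per_db


@dataclass(frozen=True)
class AcousticCondition:
    """One presentation condition.

    ``snr is None`` means the quiet condition: accuracy is driven by the
    absolute presentation level. Otherwise accuracy is driven by the SNR,
    degraded by the reverberation time ``rt`` (seconds).
    """

    level: float | None = None
    snr: float | None = None
    rt: float = 0.0

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"reverberation time must be >= 0, got {self.rt}")
        if self.level is None and self.snr is None:
            raise ValueError("condition needs a presentation level or an SNR")

    @property
    def is_quiet(self) -> bool:
        return self.snr is None


#: default token pool for substitutions/insertions
_DEFAULT_VOCAB = tuple(
    "de het een en ik je niet van dat die in op te zijn er maar dan ook".split()
) + tuple(str(d) for d in range(10))


@dataclass
class TranscriberModel:
    """Simulated transcriber with logistic level/SNR dependence.

    Parameters
    ----------
    srt_quiet : float
        Presentation level (dB SPL) of 50% token accuracy in quiet.
    slope_quiet : float
        Psychometric slope at the quiet midpoint, %/dB.
    srt_noise : float
        SNR (dB) of 50% token accuracy in noise.
    slope_noise : float
        Psychometric slope at the noise midpoint, %/dB.
    p_floor : float
        Guess/lapse floor: accuracy approaches ``p_floor`` (not 0) at very
        adverse drive. Default 0.
    error_mix : (float, float)
        (substitution, deletion) proportions among incorrect tokens; must sum
        to 1.
    insertion_rate : float
        Expected inserted tokens per stimulus token (Poisson).
    rt_penalty : float
        Effective-SNR loss in dB per second of reverberation time.
    vocabulary : sequence of str
        Token pool for substitutions and insertions.
    seed : int
        Base seed for reproducible responses.
    """

    srt_quiet: float = 55.0
    slope_quiet: float = 5.0
    srt_noise: float = 8.0
    slope_noise: float = 8.0
    p_floor: float = 0.0
    error_mix: tuple[float, float] = (0.7, 0.3)
    insertion_rate: float = 0.0
    rt_penalty: float = 2.0
    vocabulary: tuple[str, ...] = _DEFAULT_VOCAB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope_quiet <= 0 or self.slope_noise <= 0:
            raise ValueError("psychometric slopes must be > 0")
        if not 0.0 <= self.p_floor < 1.0:
            raise ValueError(f"p_floor must be in [0, 1), got {self.p_floor}")
        sub, dele = self.error_mix
        if not (0 <= sub <= 1 and 0 <= dele <= 1) or abs(sub + dele - 1.0) > 1e-9:
            raise ValueError(f"error_mix proportions must sum to 1, got {self.error_mix}")
        if self.insertion_rate < 0:
            raise ValueError("insertion_rate must be >= 0")
        if self.rt_penalty < 0:
            raise ValueError("rt_penalty must be >= 0")
        self.vocabulary = tuple(self.vocabulary)
        if len(self.vocabulary) < 2:
            raise ValueError("vocabulary needs at least 2 tokens for substitutions")
        self._call_counter = 0

    # -- psychometric core ---------------------------------------------------

    def drive(self, cond: AcousticCondition) -> float:
        """Effective stimulus drive in dB (level in quiet, penalized SNR in noise)."""
        if cond.is_quiet:
            if cond.level is None:
                raise ValueError("quiet condition requires a presentation level")
            return float(cond.level)
        return float(cond.snr) - self.rt_penalty * cond.rt

    def token_accuracy(self, cond: AcousticCondition) -> float:
        """Probability of transcribing one token correctly under ``cond``."""
        if cond.is_quiet:
            mid, scale = self.srt_quiet, slope_to_scale(self.slope_quiet)
        else:
            mid, scale = self.srt_noise, slope_to_scale(self.slope_noise)
        core = float(expit((self.drive(cond) - mid) / scale))
        return self.p_floor + (1.0 - self.p_floor) * core

    # -- response generation -------------------------------------------------

    def reset(self) -> None:
        """Reset the internal call counter (restores response sequence)."""
        self._call_counter = 0

    def transcribe(
        self,
        stimulus: Sequence[str],
        cond: AcousticCondition,
        call_key: int | None = None,
    ) -> tuple[str, ...]:
        """Produce a token response to ``stimulus`` under ``cond``.

        ``call_key`` overrides the internal call counter, enabling common
        random numbers across conditions; by default successive calls use
        successive counters.
        """
        stimulus = tuple(stimulus)
        if not stimulus:
            raise ValueError("stimulus must be non-empty")
        if call_key is None:
            call_key = self._call_counter
            self._call_counter += 1
        rng_correct = np.random.default_rng([self.seed & 0x7FFFFFFF, call_key, 0])
        rng_error = np.random.default_rng([self.seed & 0x7FFFFFFF, call_key, 1])
        rng_insert = np.random.default_rng([self.seed & 0x7FFFFFFF, call_key, 2])

        p = self.token_accuracy(cond)
        u = rng_correct.uniform(size=len(stimulus))
        n_ins = rng_insert.poisson(self.insertion_rate, size=len(stimulus))
        p_sub = self.error_mix[0]
        out: list[str] = []
        for tok, u_i, k_ins in zip(stimulus, u, n_ins):
            if u_i < p:
                out.append(tok)
            elif rng_error.uniform() < p_sub:
                out.append(self._other_token(tok, rng_error))
            # else: deletion — token dropped
            for _ in range(int(k_ins)):
                out.append(self.vocabulary[int(rng_insert.integers(len(self.vocabulary)))])
        return tuple(out)

    def _other_token(self, token: str, rng: np.random.Generator) -> str:
        while True:
            cand = self.vocabulary[int(rng.integers(len(self.vocabulary)))]
            if cand != token:
                return cand

    def __call__(self, stimulus: Sequence[str], cond: AcousticCondition) -> tuple[str, ...]:
        return self.transcribe(stimulus, cond)

    def with_seed(self, seed: int) -> "TranscriberModel":
        """A copy of this model with a fresh seed and reset call counter."""
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Simple responders for staircase validation and closed-form tests
# ---------------------------------------------------------------------------


class PerfectResponder:
    """Echoes the stimulus verbatim — accuracy 1 everywhere."""

    def __call__(self, stimulus: Sequence[str], cond: AcousticCondition) -> tuple[str, ...]:
        return tuple(stimulus)


class SilentResponder:
    """Returns an empty transcript — accuracy 0 everywhere."""

    def __call__(self, stimulus: Sequence[str], cond: AcousticCondition) -> tuple[str, ...]:
        return ()


class ThresholdResponder:
    """Deterministic step observer: correct iff drive >= threshold.

    Drive is the level in quiet, the SNR in noise (no reverberation penalty).
    """

    def __init__(self, threshold: float):
        self.threshold = threshold

    def __call__(self, stimulus: Sequence[str], cond: AcousticCondition) -> tuple[str, ...]:
        x = cond.level if cond.is_quiet else cond.snr
        return tuple(stimulus) if x >= self.threshold else ()


class LogisticItemResponder:
    """Stochastic observer whose *whole-item* success is logistic in the drive.

    Unlike :class:`TranscriberModel`, whose psychometric function applies per
    token (so whole-triplet or whole-sentence success is the product of token
    probabilities), this responder applies the logistic at the item level:
    the full stimulus is echoed with probability
    ``logistic((x - srt) / (25 / slope))`` and otherwise replaced by an empty
    transcript. This is the canonical simulated observer for staircase
    parameter recovery, where the ground truth must be the item-level 50%
    point that the 1-up/1-down rule targets.
    """

    def __init__(self, srt: float, slope: float, seed: int = 0, quiet: bool = False):
        self.srt = float(srt)
        self.scale = slope_to_scale(slope)
        self.quiet = quiet
        self._rng = np.random.default_rng(seed)

    def __call__(self, stimulus: Sequence[str], cond: AcousticCondition) -> tuple[str, ...]:
        x = cond.level if self.quiet else cond.snr
        if x is None:
            raise ValueError("condition lacks the drive this responder listens to")
        p = float(expit((x - self.srt) / self.scale))
        return tuple(stimulus) if self._rng.uniform() < p else ()
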