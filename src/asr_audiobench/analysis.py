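"""Post-session analysis.

* logistic psychometric ("speech audiogram") fitting, exposed both as a
  statsmodels-style model/results pair (:class:`SpeechAudiogram` →
  :class:`SpeechAudiogramResults`) and as the convenience function
  :func:`fit_psychometric`;
* SRT extraction from a fitted curve at an arbitrary percent-correct
  criterion;
* test–retest reliability: Bland–Altman bias and limits of agreement, and the
  root-mean-square difference (RMSD);
* the WER(SNR, RT) grid — word error rate of a simulated transcriber over a
  grid of signal-to-noise ratios and reverberation times, the
  ecologically-oriented summary metric — with a pluggable semantic-distance
  hook so embedding-based measures can replace WER without touching the grid
  machinery.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .scoring import word_error_rate
from .stimuli import Dialogue
from .transcriber import AcousticCondition, TranscriberModel, slope_to_scale

__all__ = [
    "PsychometricCurve",
    "FitFailure",
    "SpeechAudiogram",
    "SpeechAudiogramResults",
    "fit_psychometric",
    "srt_from_curve",
    "ReliabilityReport",
    "bland_altman",
    "rmsd",
    "WerGrid",
    "wer_grid",
    "SemanticDistanceHook",
    "semantic_distance_default",
]


# ---------------------------------------------------------------------------
# Psychometric curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsychometricCurve:
    """Logistic percent-correct curve.

    ``midpoint`` is the stimulus value (dB) of 50% between floor and ceiling —
    the SRT when floor/ceiling are 0/100; ``slope`` is the derivative of the
    percent curve at the midpoint in %/dB.
    """

    midpoint: float
    slope: float
    floor: float = 0.0
    ceiling: float = 100.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if not self.floor < self.ceiling:
            raise ValueError("floor must be below ceiling")

    def _scale(self) -> float:
        # slope of range*logistic((x-m)/s) at m is range/(4s) %/dB
        return (self.ceiling - self.floor) / (4.0 * self.slope)

    def predict(self, x) -> np.ndarray:
        """Percent correct at stimulus value(s) ``x``."""
        x = np.asarray(x, dtype=float)
        return self.floor + (self.ceiling - self.floor) * expit(
            (x - self.midpoint) / self._scale()
        )

    def inverse(self, percent: float) -> float:
        """Stimulus value at which the curve crosses ``percent``."""
        if not self.floor < percent < self.ceiling:
            raise ValueError(
                f"criterion {percent} outside the open interval "
                f"({self.floor}, {self.ceiling})"
            )
        q = (percent - self.floor) / (self.ceiling - self.floor)
        return self.midpoint + self._scale() * float(logit(q))


class FitFailure(RuntimeError):
    """Psychometric fit did not converge or the data cannot identify a curve."""


class SpeechAudiogram:
    """Logistic speech-audiogram model for (level, percent-correct) points.

    Least-squares fit of the 2-parameter logistic with asymptotes fixed at
    0 and 100%, matching how clinical speech audiograms are interpolated
    through aggregate test–retest points. Construct from arrays or with
    :meth:`from_points` / :meth:`from_dataframe`, then call :meth:`fit`.
    """

    def __init__(self, levels: Sequence[float], percents: Sequence[float],
                 floor: float = 0.0, ceiling: float = 100.0):
        self.levels = np.asarray(levels, dtype=float)
        self.percents = np.asarray(percents, dtype=float)
        self.floor = float(floor)
        self.ceiling = float(ceiling)
        if self.levels.shape != self.percents.shape or self.levels.ndim != 1:
            raise ValueError("levels and percents must be 1-D arrays of equal length")
        # two symmetric points determine the two parameters exactly, so 2 is
        # the hard minimum; 3+ distinct levels are needed for any redundancy
        if len(np.unique(self.levels)) < 2:
            raise ValueError("need at least 2 distinct levels to fit a logistic")
        if np.any((self.percents < self.floor - 1e-9) | (self.percents > self.ceiling + 1e-9)):
            raise ValueError("percent values must lie within [floor, ceiling]")

    @classmethod
    def from_points(cls, points: Sequence[tuple[float, float]], **kw) -> "SpeechAudiogram":
        xs, ys = zip(*points)
        return cls(xs, ys, **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, level_col: str = "level",
                       percent_col: str = "percent", **kw) -> "SpeechAudiogram":
        return cls(df[level_col].to_numpy(), df[percent_col].to_numpy(), **kw)

    def _initial_guess(self) -> tuple[float, float]:
        # midpoint: level closest to the half-way percent; scale from the span
        half = (self.floor + self.ceiling) / 2.0
        mid = float(self.levels[np.argmin(np.abs(self.percents - half))])
        span = float(self.levels.max() - self.levels.min())
        scale = max(span / 4.0, 1e-3)
        return mid, scale

    def fit(self) -> "SpeechAudiogramResults":
        """Fit (midpoint, scale) by least squares; tolerance 1e-8 on parameters."""
        if np.ptp(self.percents) == 0:
            raise FitFailure(
                "all percent values identical: the data carry no level dependence"
            )
        rng = self.ceiling - self.floor

        def residuals(theta: np.ndarray) -> np.ndarray:
            mid, log_scale = theta
            pred = self.floor + rng * expit((self.levels - mid) / np.exp(log_scale))
            return pred - self.percents

        mid0, scale0 = self._initial_guess()
        sol = least_squares(
            residuals, x0=[mid0, np.log(scale0)], xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
        if not sol.success:
            raise FitFailure(f"least-squares fit did not converge: {sol.message}")
        mid, scale = float(sol.x[0]), float(np.exp(sol.x[1]))
        curve = PsychometricCurve(
            midpoint=mid, slope=rng / (4.0 * scale), floor=self.floor, ceiling=self.ceiling
        )
        # asymptotic covariance of (midpoint, scale) from the Jacobian
        n, k = len(self.levels), 2
        dof = max(n - k, 1)
        resid = sol.fun
        s2 = float(resid @ resid) / dof
        J = sol.jac @ np.diag([1.0, 1.0 / scale])  # chain rule: d/d scale = d/d log scale / scale
        JTJ = J.T @ J
        try:
            cov = s2 * np.linalg.inv(JTJ)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        return SpeechAudiogramResults(model=self, curve=curve, cov_params=cov,
                                      residuals=resid, n_obs=n)


@dataclass(frozen=True)
class SpeechAudiogramResults:
    """Fitted speech audiogram: curve, uncertainties and diagnostics."""

    model: SpeechAudiogram
    curve: PsychometricCurve
    cov_params: np.ndarray
    residuals: np.ndarray
    n_obs: int

    @property
    def params(self) -> dict[str, float]:
        return {"midpoint": self.curve.midpoint, "slope": self.curve.slope}

    @property
    def bse(self) -> dict[str, float]:
        """Approximate standard errors of midpoint and slope (delta method)."""
        se_mid = float(np.sqrt(self.cov_params[0, 0]))
        scale = (self.curve.ceiling - self.curve.floor) / (4.0 * self.curve.slope)
        # slope = range/(4 scale) -> d slope/d scale = -slope/scale
        se_slope = float(np.sqrt(self.cov_params[1, 1])) * self.curve.slope / scale
        return {"midpoint": se_mid, "slope": se_slope}

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))

    def srt(self, criterion: float = 50.0) -> float:
        return srt_from_curve(self.curve, criterion)

    def predict(self, x) -> np.ndarray:
        return self.curve.predict(x)

    def summary(self) -> str:
        bse = self.bse
        lines = [
            "Speech audiogram (logistic psychometric fit)",
            "=" * 46,
            f"{'n obs':<22}{self.n_obs:>10d}",
            f"{'floor / ceiling (%)':<22}{self.curve.floor:>4.0f} / {self.curve.ceiling:.0f}",
            f"{'midpoint (dB, SRT50)':<22}{self.curve.midpoint:>10.3f}  (se {bse['midpoint']:.3f})",
            f"{'slope (%/dB)':<22}{self.curve.slope:>10.3f}  (se {bse['slope']:.3f})",
            f"{'residual RMSE (%)':<22}{self.rmse:>10.3f}",
        ]
        return "\n".join(lines)


def fit_psychometric(points: Sequence[tuple[float, float]]) -> PsychometricCurve:
    """Fit a 0–100% logistic through (level dB, percent) points.

    Convenience wrapper over :class:`SpeechAudiogram`; returns the fitted
    :class:`PsychometricCurve`.
    """
    return SpeechAudiogram.from_points(points).fit().curve


def srt_from_curve(curve: PsychometricCurve, criterion: float = 50.0) -> float:
    """Stimulus value where the curve crosses ``criterion`` percent.

    Equals the midpoint exactly for criterion 50 with 0/100 asymptotes.
    """
    return curve.inverse(criterion)


# ---------------------------------------------------------------------------
# Test–retest reliability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReliabilityReport:
    """Bland–Altman agreement summary of paired test–retest measurements."""

    bias: float
    loa_low: float
    loa_high: float
    rmsd: float
    n_pairs: int
    sd_diff: float
    means: tuple[float, ...]
    differences: tuple[float, ...]


def bland_altman(pairs: Sequence[tuple[float, float]]) -> ReliabilityReport:
    """Bland–Altman analysis of (test, retest) pairs.

    bias = mean(test - retest); limits of agreement = bias ± 1.96·SD of the
    differences (n-1 denominator). The (mean, difference) points for the
    agreement plot are returned alongside.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (test, retest) pairs")
    diff = arr[:, 0] - arr[:, 1]
    mean = arr.mean(axis=1)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return ReliabilityReport(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        rmsd=float(np.sqrt(np.mean(diff**2))),
        n_pairs=len(diff),
        sd_diff=sd,
        means=tuple(mean.tolist()),
        differences=tuple(diff.tolist()),
    )


def rmsd(pairs: Sequence[tuple[float, float]]) -> float:
    """Root-mean-square difference of (test, retest) pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("need at least 1 (test, retest) pair")
    diff = arr[:, 0] - arr[:, 1]
    return float(np.sqrt(np.mean(diff**2)))


# ---------------------------------------------------------------------------
# WER(SNR, RT) grid and semantic-distance hook
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SemanticDistanceHook:
    """Named transcript-dissimilarity measure in [0, 1]; distance(x, x) = 0."""

    name: str
    distance: Callable[[Sequence[str], Sequence[str]], float]


def semantic_distance_default(ref: Sequence[str], hyp: Sequence[str]) -> float:
    """Bag-of-words Dice dissimilarity: 1 - 2|ref ∩ hyp| / (|ref| + |hyp|).

    A deliberately embedding-free stand-in for semantic distance; identical
    transcripts score 0, transcripts with disjoint vocabularies score 1. An
    empty hypothesis scores 1.
    """
    ref = tuple(ref)
    hyp = tuple(hyp)
    if not ref:
        raise ValueError("reference must be non-empty")
    if not hyp:
        return 1.0
    overlap = sum((Counter(ref) & Counter(hyp)).values())
    return 1.0 - 2.0 * overlap / (len(ref) + len(hyp))


DICE_HOOK = SemanticDistanceHook(name="bag-dice", distance=semantic_distance_default)


@dataclass(frozen=True)
class WerGrid:
    """Mean transcript-error metric over an SNR x RT condition grid."""

    snr_values: tuple[float, ...]
    rt_values: tuple[float, ...]
    wer: np.ndarray  # shape (len(snr_values), len(rt_values))
    n_tokens: int
    n_reps: int
    metric_name: str = "wer"

    def __post_init__(self) -> None:
        wer = np.asarray(self.wer, dtype=float)
        if wer.shape != (len(self.snr_values), len(self.rt_values)):
            raise ValueError(
                f"grid shape {wer.shape} does not match "
                f"{len(self.snr_values)} SNRs x {len(self.rt_values)} RTs"
            )
        object.__setattr__(self, "wer", wer)

    def to_dataframe(self) -> pd.DataFrame:
        """Rows = SNR (dB), columns = RT (s)."""
        return pd.DataFrame(
            self.wer,
            index=pd.Index(self.snr_values, name="snr_db"),
            columns=pd.Index(self.rt_values, name="rt_s"),
        )


def wer_grid(
    model: TranscriberModel,
    dialogue: Dialogue,
    snrs: Sequence[float] = (-5.0, 10.0, 30.0),
    rts: Sequence[float] = (0.0, 0.5, 2.5),
    n_reps: int = 200,
    seed: int = 0,
    metric: Callable[[Sequence[str], Sequence[str]], float] | None = None,
) -> WerGrid:
    """Mean WER of ``model`` transcribing ``dialogue`` over an SNR x RT grid.

    Default grids follow the representative daily-life conditions: SNRs of
    -5, +10 and +30 dB (quiet) and reverberation times of 0, 0.5 and 2.5 s
    (ideal, classroom, church). Each cell averages ``n_reps`` seeded
    repetitions; repetitions share random substreams across cells (common
    random numbers), so the grid ordering reflects the conditions, not
    sampling luck. ``metric`` replaces WER by any transcript-dissimilarity
    function, e.g. a :class:`SemanticDistanceHook` distance.
    """
    snrs = tuple(float(x) for x in snrs)
    rts = tuple(float(x) for x in rts)
    if not snrs or not rts:
        raise ValueError("SNR and RT grids must be non-empty")
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    fn = metric if metric is not None else word_error_rate
    sim = model.with_seed(seed & 0x7FFFFFFF)
    out = np.zeros((len(snrs), len(rts)))
    for i, snr in enumerate(snrs):
        for j, rt in enumerate(rts):
            cond = AcousticCondition(level=None, snr=snr, rt=rt)
            total = 0.0
            for rep in range(n_reps):
                hyp = sim.transcribe(dialogue.tokens, cond, call_key=rep)
                total += fn(dialogue.tokens, hyp)
            out[i, j] = total / n_reps
    return WerGrid(
        snr_values=snrs,
        rt_values=rts,
        wer=out,
        n_tokens=len(dialogue.tokens),
        n_reps=n_reps,
        metric_name=getattr(fn, "__name__", "metric"),
    )
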