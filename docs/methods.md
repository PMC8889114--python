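# Methods

This note documents the models, estimator conventions and design choices
behind asr-audiobench: what exactly is simulated, which knobs matter, and
what the validation suite does and does not demonstrate.

## The simulated transcriber

The package evaluates speech-to-text systems with clinical speech-audiometry
procedures. Since those procedures are defined operationally (stimulus in,
token response out), any responder implementing
`responder(tokens, AcousticCondition) -> tokens` can be tested. The built-in
`TranscriberModel` is a parametric stand-in for a real captioning app whose
latent performance is a token-level psychometric function:

    p(x) = p_floor + (1 - p_floor) * logistic((x - midpoint) / s),  s = 25 / slope

* In **quiet** the drive `x` is the presentation level in dB SPL, with
  midpoint `srt_quiet` (default 55 dB SPL — the middle of the 50–60 dB range
  typical of current captioning apps) and slope `slope_quiet` (default
  5 %/dB, giving the familiar S-shaped audiogram that spans roughly
  45–85 dB SPL).
* In **noise** the drive is the effective SNR `snr - rt_penalty * rt`, with
  midpoint `srt_noise` (default +8 dB SNR, the best-app range) and slope
  `slope_noise` (default 8 %/dB). Reverberation time enters only through the
  linear penalty `rt_penalty` (default 2 dB/s): the minimal monotone model of
  a reverberation axis, isolated in a single field so a better room-acoustics
  model can replace it without touching anything else.

Incorrect tokens become substitutions or deletions according to `error_mix`
(default 70/30 — substitutions dominate in running ASR output); insertions
are Poisson with mean `insertion_rate` per stimulus token (default 0; the
battery examples use 0.02). Token errors are independent across positions.
This deliberately omits language-model context effects: a real app's
accuracy rises with linguistic redundancy, which is why its word-list scores
undershoot its sentence scores. Users can emulate that by configuring
different midpoints/slopes per test; the simulator itself stays context-free.

Determinism: each `transcribe` call derives three separate substreams
(per-token correctness, error identity, insertions) from
`(seed, call_key)`. Replaying the same `call_key` across conditions shares
the per-token luck — common random numbers — so condition contrasts such as
the WER(SNR, RT) grid are ordered by the conditions themselves, not by
sampling noise.

## Scoring conventions

**Alignment and WER.** `align` computes a unit-cost minimum-edit alignment
(dynamic programming over the full cost matrix, vectorized per row). Among
equal-cost alignments the traceback prefers match > substitution > deletion
> insertion, making all counts deterministic; e.g. "ab" vs "ba" is reported
as two substitutions, never delete+insert. WER = (S + D + I) / N_ref and can
exceed 1 with many insertions. The implementation is cross-checked in the
test suite against exhaustive enumeration of all edit scripts (every
ref/hyp pair of length ≤ 4 over a 3-token alphabet) and against an
independent edit-distance library on random longer pairs.

**CNC phoneme scoring.** Clinical scoring is manual ("count correct
phonemes, subtract insertions"); the package operationalizes it as the
alignment's matches and insertions per word, summed over the 11 scored words
of a 12-word list (denominator 33), with the percentage floored at 0 so a
response stuffed with insertions cannot go negative. Alignment-based scoring
counts a phoneme correct even when a neighbour was deleted — a generalization
of positional matching that is reproducible and yields insertion counts
naturally. Whether a human scorer would credit a correct phoneme in a
shifted position is genuinely underdetermined; the choice is isolated in
`score_cnc_word`. Phoneme segmentation (diphthongs, clusters) is a property
of the stimulus file, not of the scorer.

**Sentence scoring.** All-or-nothing equality after casefolding and
punctuation stripping. Keyword scoring — known to ease the task by about
1 dB — is out of scope beyond this note.

**Triplet scoring.** Captioning apps tend to embed digits in running
sentences ("I hear one two five now"), so the scorer first extracts digits:
numeral tokens contribute their digit runs ("125" → 1, 2, 5), configured
number-words (English and Dutch tables shipped; "een" → 1 etc.) map to
digits, and everything else is dropped. The triplet is correct iff the
extracted sequence equals the target in order.

## Staircase procedures and the SRT estimator

Both adaptive procedures implement the 1-up/1-down rule, which converges on
the 50% point of the item-level (triplet / whole-sentence) psychometric
function.

* **DIN**: 60 dB SPL noise, +6 dB initial SNR, 2 dB steps, 24 triplets,
  first 4 discarded. The estimator averages the SNRs of trials 5–24 **plus
  the SNR that would have been presented next** (the "virtual" 25th trial) —
  the standard DIN convention; `include_virtual_trial=False` switches to the
  plain mean. `sd_within_run` is the sample SD of the averaged SNRs, the
  quantity plotted as within-list error bars.
* **Plomp**: sentence 1 is re-presented ascending in 4 dB steps until
  reproduced correctly (the published first-sentence search), sentences 2–13
  then track 1-up/1-down at 2 dB; the estimator averages the presentation
  levels of sentences 5–13 plus the virtual 14th level. `quiet_mode` runs
  the identical rule on absolute level, giving the SRT in quiet; in noise the
  masker defaults to 70 dB SPL, 15–20 dB above a typical app's quiet SRT.
  All of these conventions are config fields so alternatives are testable.

**Parameter recovery.** The recovery suites drive the staircases with
`LogisticItemResponder`, whose *whole-item* success probability is logistic
in the drive — the correct ground truth for a rule that targets the
item-level 50% point (a token-level simulant's triplet SRT sits above its
token midpoint, since all three digits must be right). Recovery runs start
each track at the true SRT: the discard rule then absorbs the residual
transient, and the measured quantity is the estimator's intrinsic bias
(found to be < 0.1 dB at moderate slopes, < 0.2 dB at 5 %/dB, SD ≈ 0.6–2 dB
per run depending on slope). The start-point transient itself is a
deterministic property of the protocol and is pinned separately by the
closed-form extremes: an always-correct responder forces SRT = −22.0 dB and
an always-wrong responder +34.0 dB under the default config. Clinical-style
runs in the benchmark keep the protocol's +6 dB start; with a steep observer
far below the start (e.g. a normal-hearing −8.8 dB), the descent leaks past
the 4-trial discard and biases a single default-start run upward by roughly
+0.7 dB — a property of the protocol, not of the estimator.

## Psychometric fitting

`SpeechAudiogram` fits the 2-parameter logistic (asymptotes fixed at 0 and
100%) by least squares on the percent points, mirroring how clinical speech
audiograms are interpolated through aggregate test–retest points; binomial
MLE would weight points near the asymptotes differently but is not what the
audiogram convention does. The scale parameter is fitted on a log scale for
positivity; convergence tolerances are 1e-12 so noiseless data are recovered
to well below 1e-6. Standard errors come from the residual variance and the
Jacobian (delta method for the slope). Two symmetric points exactly determine
the two parameters and are accepted as the minimal input; all-identical
percents raise `FitFailure`. `srt_from_curve` inverts the logistic at an
arbitrary criterion (50% by default, where it equals the midpoint).

## Reliability statistics

`bland_altman` reports bias = mean(test − retest), limits of agreement
bias ± 1.96·SD (SD with n−1 denominator; the 1.96 multiplier is the
conventional 95% choice), the (mean, difference) points for plotting, and the
RMSD. For Gaussian differences the LoA cover ≈95% of points, verified at
n = 10⁴ in the suite. RMSD² = bias² + (population) variance, so RMSD ≥ |bias|
always.

## The synthetic stimulus generator

The generator reproduces the *structure* of the clinical materials — 12-word
C-N-C lists with an unscored practice item and a 33-phoneme denominator,
uniform digit triplets, 13-sentence lists of 8–9 syllables assembled from a
syllable-annotated lexicon, and dialogue transcripts of 256 (Dutch analogue)
or 248 (English analogue) tokens. It does **not** reproduce phonetic
balancing, Dutch phonology, or natural-language sentence structure: words
are drawn uniformly without replacement and sentences are random lexicon
draws. Consequently the suite validates the *procedures and estimators*
(scoring rules, staircase dynamics, fitting, reliability), not the linguistic
difficulty of real materials: a passing suite says the machinery measures a
known simulated transcriber correctly, not that a particular commercial app
would obtain any particular score.

## Problem sizes and numerical choices

Monte-Carlo suites use 500 staircase runs per condition (standard error of
the mean ≤ 0.09 dB, well inside the ±0.3 dB check), 10⁴ pairs for LoA
coverage, 10⁴ trials for binomial convergence of the simulator, and 200
repetitions × 256 tokens per WER-grid cell. The exhaustive alignment oracle
covers all 14,520 ref/hyp pairs of length ≤ 4 over a 3-token alphabet.
Degenerate inputs are defined rather than left to chance: empty references
raise (WER undefined), empty hypotheses are all-deletions, empty CNC word
responses score (0, 0), and a Plomp run whose first sentence never succeeds
aborts after a configurable number of ascents.

## Known limitations

* Token errors are independent; real ASR errors are bursty and
  context-driven. Correlated-error responders can be plugged in through the
  responder contract.
* Reverberation is a linear effective-SNR penalty; no modulation-transfer or
  room-acoustics model.
* The semantic-distance default is a bag-of-words Dice dissimilarity — a
  deliberately embedding-free placeholder establishing the hook contract;
  substantive semantic measures should be supplied by the caller.
* Quiet-mode accuracy depends on level only; hard low-level cutoffs from
  input normalization in real apps can be approximated via `p_floor` and a
  steep slope but are not modelled explicitly.
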