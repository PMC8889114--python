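"""End-to-end "benchmark a simulated transcriber" orchestration.

Replays the full four-test battery against one transcriber model:

1. speech audiogram — CNC lists at 45–85 dB SPL in quiet, phoneme-scored,
   run twice (test + retest) and summarized with a Bland–Altman block;
2. digits-in-noise — one 24-triplet staircase, test + retest, RMSD;
3. Plomp sentences — first in quiet (absolute level track), then in noise
   over a 70 dB SPL masker, test + retest in noise, RMSD;
4. dialogue transcription — WER of a free-running dialogue at conversational
   level, plus a WER(SNR, RT) grid.

One global seed is expanded into per-stage substreams via
``numpy.random.SeedSequence(seed).generate_state(...)`` (stage order is fixed
and documented in ``STAGES``), so each stage can be re-run in isolation and
the whole report is byte-reproducible from (configs, seed). Report JSON
deliberately carries no wall-clock timestamp; per-session files do.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import io as session_io
from .adaptive import (
    PlompConfig,
    StaircaseConfig,
    run_din,
    run_fixed_levels,
    run_plomp,
)
from .analysis import WerGrid, bland_altman, rmsd, wer_grid
from .scoring import word_error_rate
from .stimuli import (
    make_cnc_list,
    make_dialogue,
    make_sentence_list,
    make_triplet_series,
)
from .transcriber import AcousticCondition, TranscriberModel

__all__ = ["BatteryConfig", "BenchmarkReport", "run_benchmark", "STAGES"]

#: fixed stage order; stage i consumes substream seed i (test) and i+8 (retest)
STAGES = ("stimuli", "audiogram", "din", "plomp_quiet", "plomp_noise", "dialogue", "grid")


@dataclass(frozen=True)
class BatteryConfig:
    """Configuration of the full test battery (defaults = clinical protocol)."""

    audiogram_levels: tuple[float, ...] = (45.0, 55.0, 65.0, 75.0, 85.0)
    din: StaircaseConfig = StaircaseConfig()
    plomp_quiet: PlompConfig = PlompConfig(quiet_mode=True, start_snr_or_level=30.0)
    plomp_noise: PlompConfig = PlompConfig(quiet_mode=False, start_snr_or_level=-10.0,
                                           noise_level=70.0)
    dialogue_level: float = 72.2
    dialogue_n_words: int = 256
    grid_snrs: tuple[float, ...] = (-5.0, 10.0, 30.0)
    grid_rts: tuple[float, ...] = (0.0, 0.5, 2.5)
    grid_reps: int = 50

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("audiogram_levels", "grid_snrs", "grid_rts"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "BatteryConfig":
        d = dict(d)
        for key in ("audiogram_levels", "grid_snrs", "grid_rts"):
            if key in d:
                d[key] = tuple(d[key])
        for key, sub in (("din", StaircaseConfig),
                         ("plomp_quiet", PlompConfig), ("plomp_noise", PlompConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


@dataclass(frozen=True)
class BenchmarkReport:
    """Consolidated battery outcome for one transcriber model."""

    audiogram: tuple[tuple[float, float], ...]  # (level, percent), test run
    audiogram_retest: tuple[tuple[float, float], ...]
    din_srt: float
    din_srt_retest: float
    din_sd_within_run: float
    plomp_srt_quiet: float
    plomp_srt_noise: float
    plomp_srt_noise_retest: float
    dialogue_wer: float
    reliability: dict[str, Any]
    grid: WerGrid
    #: session file names relative to the output directory, so the report is
    #: byte-identical wherever it is written
    session_files: tuple[str, ...]
    seed: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": session_io.SCHEMA_VERSION,
            "seed": self.seed,
            "audiogram": [list(p) for p in self.audiogram],
            "audiogram_retest": [list(p) for p in self.audiogram_retest],
            "din_srt": self.din_srt,
            "din_srt_retest": self.din_srt_retest,
            "din_sd_within_run": self.din_sd_within_run,
            "plomp_srt_quiet": self.plomp_srt_quiet,
            "plomp_srt_noise": self.plomp_srt_noise,
            "plomp_srt_noise_retest": self.plomp_srt_noise_retest,
            "dialogue_wer": self.dialogue_wer,
            "reliability": self.reliability,
            "wer_grid": {
                "snr_values": list(self.grid.snr_values),
                "rt_values": list(self.grid.rt_values),
                "wer": self.grid.wer.tolist(),
                "n_tokens": self.grid.n_tokens,
                "n_reps": self.grid.n_reps,
            },
            "session_files": list(self.session_files),
        }


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


def run_benchmark(
    model: TranscriberModel | str | Path,
    battery: BatteryConfig | str | Path | None = None,
    seed: int = 0,
    out_dir: str | Path = "benchmark_out",
) -> BenchmarkReport:
    """Run the full battery for ``model`` and write sessions plus a report.

    ``model`` and ``battery`` accept in-memory objects or JSON config paths.
    Outputs under ``out_dir``: one session JSON per test, ``report.json`` and
    ``grid.csv``. Fully reproducible from (configs, seed). A stage failure
    aborts with the stage name; sessions already written are preserved.
    """
    if not isinstance(model, TranscriberModel):
        model = session_io.load_model(model)
    if battery is None:
        battery = BatteryConfig()
    elif not isinstance(battery, BatteryConfig):
        battery = BatteryConfig.from_dict(
            json.loads(Path(battery).read_text(encoding="utf-8"))
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    written: list[str] = []

    stage = "stimuli"
    try:
        stim_rng = np.random.default_rng(seeds[0])
        n_levels = len(battery.audiogram_levels)
        cnc_lists = [
            make_cnc_list(int(stim_rng.integers(2**31)), list_id=f"cnc-{i + 1}")
            for i in range(n_levels)
        ]
        triplets = make_triplet_series(int(stim_rng.integers(2**31)), battery.din.n_trials)
        triplets_retest = make_triplet_series(
            int(stim_rng.integers(2**31)), battery.din.n_trials
        )
        sentences_quiet = make_sentence_list(int(stim_rng.integers(2**31)))
        sentences_noise = make_sentence_list(int(stim_rng.integers(2**31)))
        sentences_noise_retest = make_sentence_list(int(stim_rng.integers(2**31)))
        dialogue = make_dialogue(
            int(stim_rng.integers(2**31)), n_words=battery.dialogue_n_words
        )

        stage = "audiogram"
        points = run_fixed_levels(model.with_seed(seeds[1]), cnc_lists,
                                  battery.audiogram_levels)
        points_retest = run_fixed_levels(model.with_seed(seeds[1 + 8]), cnc_lists,
                                         battery.audiogram_levels)
        path = out / "session_cnc.json"
        session_io.write_session(
            path, "cnc",
            config={"levels": list(battery.audiogram_levels)},
            trials=[],
            result={
                "points": [
                    {"level": p.level, **session_io.cnc_score_to_dict(p.score)}
                    for p in points
                ],
                "retest_points": [
                    {"level": p.level, **session_io.cnc_score_to_dict(p.score)}
                    for p in points_retest
                ],
            },
            seed=seeds[1],
        )
        written.append(path.name)

        stage = "din"
        din = run_din(model.with_seed(seeds[2]), triplets, battery.din)
        din_retest = run_din(model.with_seed(seeds[2 + 8]), triplets_retest, battery.din)
        path = out / "session_din.json"
        session_io.write_session(
            path, "din",
            config=dataclasses.asdict(battery.din),
            trials=din.trials,
            result=session_io.srt_result_to_dict(din),
            seed=seeds[2],
        )
        written.append(path.name)

        stage = "plomp_quiet"
        plomp_q = run_plomp(model.with_seed(seeds[3]), sentences_quiet,
                            battery.plomp_quiet)
        path = out / "session_plomp_quiet.json"
        session_io.write_session(
            path, "plomp",
            config=dataclasses.asdict(battery.plomp_quiet),
            trials=plomp_q.trials,
            result=session_io.srt_result_to_dict(plomp_q),
            seed=seeds[3],
        )
        written.append(path.name)

        stage = "plomp_noise"
        plomp_n = run_plomp(model.with_seed(seeds[4]), sentences_noise,
                            battery.plomp_noise)
        plomp_n_retest = run_plomp(model.with_seed(seeds[4 + 8]),
                                   sentences_noise_retest, battery.plomp_noise)
        path = out / "session_plomp_noise.json"
        session_io.write_session(
            path, "plomp",
            config=dataclasses.asdict(battery.plomp_noise),
            trials=plomp_n.trials,
            result=session_io.srt_result_to_dict(plomp_n),
            seed=seeds[4],
        )
        written.append(path.name)

        stage = "dialogue"
        sim = model.with_seed(seeds[5])
        cond = AcousticCondition(level=battery.dialogue_level, snr=None, rt=0.0)
        hyp = sim.transcribe(dialogue.tokens, cond)
        dialogue_wer = word_error_rate(dialogue.tokens, hyp)
        path = out / "session_dialogue.json"
        session_io.write_session(
            path, "dialogue",
            config={"level": battery.dialogue_level,
                    "n_words": battery.dialogue_n_words,
                    "language_tag": dialogue.language_tag},
            trials=[],
            result={"wer": dialogue_wer, "hyp_length": len(hyp)},
            seed=seeds[5],
        )
        written.append(path.name)

        stage = "grid"
        grid = wer_grid(model, dialogue, battery.grid_snrs, battery.grid_rts,
                        n_reps=battery.grid_reps, seed=seeds[6])
        grid.to_dataframe().to_csv(out / "grid.csv")

        stage = "report"
        ba = bland_altman(
            [(p.percent, q.percent) for p, q in zip(points, points_retest)]
        )
        reliability = {
            "cnc_bland_altman": {
                "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                "rmsd": ba.rmsd, "n_pairs": ba.n_pairs,
            },
            "din_rmsd": rmsd([(din.srt, din_retest.srt)]),
            "plomp_noise_rmsd": rmsd([(plomp_n.srt, plomp_n_retest.srt)]),
        }
        report = BenchmarkReport(
            audiogram=tuple((p.level, p.percent) for p in points),
            audiogram_retest=tuple((p.level, p.percent) for p in points_retest),
            din_srt=din.srt,
            din_srt_retest=din_retest.srt,
            din_sd_within_run=din.sd_within_run,
            plomp_srt_quiet=plomp_q.srt,
            plomp_srt_noise=plomp_n.srt,
            plomp_srt_noise_retest=plomp_n_retest.srt,
            dialogue_wer=dialogue_wer,
            reliability=reliability,
            grid=grid,
            session_files=tuple(written),
            seed=seed,
        )
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8"
        )
        return report
    except Exception as exc:
        raise RuntimeError(
            f"benchmark stage {stage!r} failed: {exc}; "
            f"sessions already written: {written or 'none'}"
        ) from exc
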