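"""Session/report file formats, model configs, and validation.

Sessions are JSON documents with a fixed envelope::

    {
      "schema_version": "1",
      "test_kind": "cnc" | "din" | "plomp" | "dialogue",
      "config": {...},          # the procedure config that produced the run
      "trials": [{...}, ...],   # every presentation, in order
      "result": {...},          # score / SRT object, shape depends on test_kind
      "seed": 7,
      "timestamp": "2026-01-01T00:00:00+00:00"
    }

Stimulus lists and grid matrices travel as CSV (see :mod:`.stimuli` and
:class:`~asr_audiobench.analysis.WerGrid`); everything is human-inspectable
and diff-friendly.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Sequence

from .adaptive import PlompConfig, SrtResult, StaircaseConfig, Trial
from .scoring import CncScore
from .transcriber import TranscriberModel

__all__ = [
    "SCHEMA_VERSION",
    "TEST_KINDS",
    "load_model",
    "save_model",
    "trial_to_dict",
    "trial_from_dict",
    "srt_result_to_dict",
    "cnc_score_to_dict",
    "write_session",
    "read_session",
    "validate_files",
]

SCHEMA_VERSION = "1"
TEST_KINDS = ("cnc", "din", "plomp", "dialogue")

_REQUIRED_KEYS = ("schema_version", "test_kind", "config", "trials", "result", "seed")


# ---------------------------------------------------------------------------
# Model configs
# ---------------------------------------------------------------------------

def save_model(model: TranscriberModel, path: str | Path) -> None:
    """Write a transcriber model config as JSON (exactly the model fields)."""
    fields = {f.name: getattr(model, f.name) for f in dataclasses.fields(model)}
    fields["error_mix"] = list(fields["error_mix"])
    fields["vocabulary"] = list(fields["vocabulary"])
    Path(path).write_text(json.dumps(fields, indent=2) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> TranscriberModel:
    """Load a transcriber model config written by :func:`save_model`."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if "error_mix" in data:
        data["error_mix"] = tuple(data["error_mix"])
    if "vocabulary" in data:
        data["vocabulary"] = tuple(data["vocabulary"])
    return TranscriberModel(**data)


# ---------------------------------------------------------------------------
# Session serialization
# ---------------------------------------------------------------------------

def trial_to_dict(t: Trial) -> dict[str, Any]:
    return {
        "index": t.index,
        "stimulus_ref": t.stimulus_ref,
        "snr_or_level": t.snr_or_level,
        "response_tokens": list(t.response_tokens),
        "correct": t.correct,
    }


def trial_from_dict(d: dict[str, Any]) -> Trial:
    return Trial(
        index=int(d["index"]),
        stimulus_ref=str(d["stimulus_ref"]),
        snr_or_level=float(d["snr_or_level"]),
        response_tokens=tuple(d["response_tokens"]),
        correct=bool(d["correct"]),
    )


def srt_result_to_dict(r: SrtResult) -> dict[str, Any]:
    return {
        "srt": r.srt,
        "sd_within_run": r.sd_within_run,
        "averaged_levels": list(r.averaged_levels),
        "virtual_level": r.virtual_level,
    }


def cnc_score_to_dict(s: CncScore) -> dict[str, Any]:
    return {
        "phonemes_correct": s.phonemes_correct,
        "phonemes_inserted": s.phonemes_inserted,
        "denominator": s.denominator,
        "percent": s.percent,
    }


def write_session(
    path: str | Path,
    test_kind: str,
    config: dict[str, Any],
    trials: Sequence[Trial],
    result: dict[str, Any],
    seed: int,
    timestamp: str | None = None,
) -> None:
    """Write one session file; ``timestamp`` defaults to now (UTC, ISO-8601)."""
    if test_kind not in TEST_KINDS:
        raise ValueError(f"test_kind must be one of {TEST_KINDS}, got {test_kind!r}")
    doc = {
        "schema_version": SCHEMA_VERSION,
        "test_kind": test_kind,
        "config": config,
        "trials": [trial_to_dict(t) for t in trials],
        "result": result,
        "seed": int(seed),
        "timestamp": timestamp or datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_session(path: str | Path) -> dict[str, Any]:
    """Parse and minimally validate a session file; raises on malformed input."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    missing = [k for k in _REQUIRED_KEYS if k not in doc]
    if missing:
        raise ValueError(f"{path}: session missing required keys {missing}")
    if doc["test_kind"] not in TEST_KINDS:
        raise ValueError(f"{path}: unknown test_kind {doc['test_kind']!r}")
    return doc


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _validate_session_doc(path: str, doc: dict[str, Any]) -> list[str]:
    problems: list[str] = []
    for key in _REQUIRED_KEYS:
        if key not in doc:
            problems.append(f"{path}: missing required key {key!r}")
    if problems:
        return problems
    if doc["schema_version"] != SCHEMA_VERSION:
        problems.append(
            f"{path}: unsupported schema_version {doc['schema_version']!r}"
        )
    kind = doc["test_kind"]
    if kind not in TEST_KINDS:
        problems.append(f"{path}: unknown test_kind {kind!r}")
        return problems
    trials = doc["trials"]
    for i, t in enumerate(trials):
        for key in ("index", "stimulus_ref", "snr_or_level", "response_tokens", "correct"):
            if key not in t:
                problems.append(f"{path}: trial {i + 1} missing field {key!r}")
    if problems:
        return problems

    if kind in ("din", "plomp"):
        step = float(doc["config"].get("step", 0))
        # staircase laws: consecutive presentations differ by exactly one step,
        # downward after a correct trial, upward after an incorrect one
        # (Plomp sentence-1 search uses first_sentence_step upward instead)
        first_step = float(doc["config"].get("first_sentence_step", step))
        for prev, cur in zip(trials, trials[1:]):
            gap = float(cur["snr_or_level"]) - float(prev["snr_or_level"])
            in_search = kind == "plomp" and cur["stimulus_ref"] == trials[0]["stimulus_ref"]
            allowed = first_step if in_search else step
            if abs(abs(gap) - allowed) > 1e-9:
                problems.append(
                    f"{path}: trial {cur['index']}: level gap {gap:+g} dB "
                    f"!= configured step {allowed:g} dB"
                )
            elif not in_search and gap != 0:
                went_down = gap < 0
                if went_down != bool(prev["correct"]):
                    problems.append(
                        f"{path}: trial {cur['index']}: direction law violated "
                        f"(previous trial correct={prev['correct']}, gap {gap:+g})"
                    )
        result = doc["result"]
        if "srt" not in result:
            problems.append(f"{path}: {kind} result lacks 'srt'")
    elif kind == "cnc":
        result = doc["result"]
        for point in result.get("points", []):
            denom = point.get("denominator")
            if denom is not None and denom % 3 != 0:
                problems.append(
                    f"{path}: CNC denominator {denom} is not a multiple of 3"
                )
    return problems


def validate_files(paths: Iterable[str | Path]) -> list[str]:
    """Schema validation for session files; returns human-readable diagnostics.

    An empty list means every file is valid. Unreadable files raise ``OSError``;
    malformed JSON and schema violations are reported as diagnostics with
    position information where available.
    """
    problems: list[str] = []
    for path in paths:
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            problems.append(
                f"{path}: JSON parse error at line {exc.lineno} column {exc.colno}: {exc.msg}"
            )
            continue
        if not isinstance(doc, dict):
            problems.append(f"{path}: session document must be a JSON object")
            continue
        problems.extend(_validate_session_doc(str(path), doc))
    return problems
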