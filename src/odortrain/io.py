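"""Reading and writing session records and cross-session summaries.

A session is stored as a directory of two plain-text files:

``events.jsonl``
    Line-delimited JSON.  The first line is a provenance header (schema
    version, configuration snapshot, seed, phase, totals, termination);
    every following line is one event ``{"t_ms": ..., "event": ..., ...}``.
    Line-delimited text mirrors the serial event stream the rig produces
    and keeps fixtures diff-able.

``trials.csv``
    One row per trial: identity, odor sequence, timing, outcome, lick
    times (integer ms, semicolon-separated) and reward.

Round trips are lossless: all times are integer milliseconds.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .core import Event, SessionConfig, SessionRecord, TrialResult, TrialSpec
from .analysis import block_stats_frame

__all__ = ["write_session", "read_session", "summarize", "SessionParseError"]

SCHEMA = "odortrain-session/1"

_TRIAL_FIELDS = [
    "trial_index",
    "paradigm",
    "sample_odor",
    "test_odor",
    "trial_type",
    "outcome",
    "n_licks",
    "reward_uL",
    "t_start_ms",
    "odor_duration_ms",
    "delay_ms",
    "window_start_ms",
    "window_end_ms",
    "iti_ms",
    "mode",
    "lick_times_ms",
]


class SessionParseError(ValueError):
    """Raised when a stored session fails to parse; names the bad line."""


def _dump(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def write_session(record: SessionRecord, path: Union[str, Path]) -> Path:
    """Write a session to directory ``path``; returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "schema": SCHEMA,
        "version": __version__,
        "config": record.config.to_dict(),
        "phase": record.phase,
        "seed": record.seed,
        "totals": record.totals,
        "termination_reason": record.termination_reason,
        "partial": record.partial,
        "n_events": len(record.events),
    }
    with open(path / "events.jsonl", "w") as fh:
        fh.write(_dump(header) + "\n")
        for ev in record.events:
            fh.write(_dump(ev.to_dict()) + "\n")
    with open(path / "trials.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_TRIAL_FIELDS)
        w.writeheader()
        for r in record.results:
            s = r.spec
            w.writerow(
                {
                    "trial_index": s.index,
                    "paradigm": s.paradigm,
                    "sample_odor": s.sample_odor,
                    "test_odor": s.test_odor or "",
                    "trial_type": s.trial_type,
                    "outcome": r.outcome,
                    "n_licks": len(r.lick_times_ms),
                    "reward_uL": r.reward_uL,
                    "t_start_ms": r.t_start_ms,
                    "odor_duration_ms": round(s.odor_duration_s * 1000),
                    "delay_ms": "" if s.delay_s is None else round(s.delay_s * 1000),
                    "window_start_ms": round(s.response_window_s[0] * 1000),
                    "window_end_ms": round(s.response_window_s[1] * 1000),
                    "iti_ms": round(s.iti_s * 1000),
                    "mode": r.mode or "",
                    "lick_times_ms": ";".join(str(t) for t in r.lick_times_ms),
                }
            )
    return path


def _parse_events(path: Path) -> tuple[dict, list[Event]]:
    events: list[Event] = []
    header: Optional[dict] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SessionParseError(
                    f"{path}: malformed JSON at line {lineno} "
                    f"(last good line: {lineno - 1}): {exc}"
                ) from exc
            if lineno == 1:
                header = obj
                if obj.get("schema") != SCHEMA:
                    raise SessionParseError(
                        f"{path}: schema mismatch: expected {SCHEMA!r}, "
                        f"got {obj.get('schema')!r}"
                    )
                continue
            try:
                t_ms = obj.pop("t_ms")
                kind = obj.pop("event")
            except KeyError as exc:
                raise SessionParseError(
                    f"{path}: line {lineno} missing field {exc}"
                ) from exc
            events.append(Event(int(t_ms), kind, obj))
    if header is None:
        raise SessionParseError(f"{path}: empty event file")
    if header.get("n_events") is not None and header["n_events"] != len(events):
        raise SessionParseError(
            f"{path}: truncated event log: header promises "
            f"{header['n_events']} events, found {len(events)} "
            f"(last good line: {len(events) + 1})"
        )
    return header, events


def _parse_trial_row(row: dict, lineno: int, path: Path) -> TrialResult:
    try:
        spec = TrialSpec(
            index=int(row["trial_index"]),
            paradigm=row["paradigm"],
            sample_odor=row["sample_odor"],
            test_odor=row["test_odor"] or None,
            trial_type=row["trial_type"],
            odor_duration_s=int(row["odor_duration_ms"]) / 1000.0,
            delay_s=int(row["delay_ms"]) / 1000.0 if row["delay_ms"] else None,
            response_window_s=(
                int(row["window_start_ms"]) / 1000.0,
                int(row["window_end_ms"]) / 1000.0,
            ),
            iti_s=int(row["iti_ms"]) / 1000.0,
        )
        licks = tuple(
            int(t) for t in row["lick_times_ms"].split(";") if t != ""
        )
        return TrialResult(
            spec=spec,
            outcome=row["outcome"],
            lick_times_ms=licks,
            reward_uL=float(row["reward_uL"]),
            t_start_ms=int(row["t_start_ms"]),
            mode=row["mode"] or None,
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise SessionParseError(f"{path}: bad trial row at line {lineno}: {exc}") from exc


def read_session(path: Union[str, Path]) -> SessionRecord:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    header, events = _parse_events(path / "events.jsonl")
    results: list[TrialResult] = []
    with open(path / "trials.csv", newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            results.append(_parse_trial_row(row, lineno, path))
    return SessionRecord(
        config=SessionConfig.from_dict(header["config"]),
        phase=header["phase"],
        seed=header["seed"],
        events=events,
        results=results,
        totals=header["totals"],
        termination_reason=header["termination_reason"],
        partial=header.get("partial", False),
    )


def summarize(
    records: Sequence[SessionRecord], block_size: int = 24
) -> pd.DataFrame:
    """Per-block mean +/- SEM of performance and rates across sessions.

    Each record contributes one value per block; rows are blocks, columns
    are ``<metric>_mean`` and ``<metric>_sem`` with ``n`` the number of
    sessions contributing to the block (N = number of simulated animals).
    Sessions must share one paradigm.
    """
    if not records:
        raise ValueError("need at least one record")
    paradigms = {r.config.paradigm for r in records}
    if len(paradigms) > 1:
        raise ValueError(f"mixed paradigms in one summary group: {sorted(paradigms)}")
    frames = []
    for i, rec in enumerate(records):
        df = block_stats_frame(rec.results, block_size)
        df = df[df["complete"]]
        df["session"] = i
        frames.append(df)
    longf = pd.concat(frames, ignore_index=True)
    metrics = ["performance", "hit_rate", "false_choice_rate", "cr_rate", "d_prime"]
    grouped = longf.groupby("block_index")
    out = pd.DataFrame({"n": grouped["session"].count()})
    for m in metrics:
        out[f"{m}_mean"] = grouped[m].mean()
        sem = grouped[m].std(ddof=1) / np.sqrt(grouped[m].count())
        out[f"{m}_sem"] = sem.fillna(0.0)
    return out.reset_index()
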