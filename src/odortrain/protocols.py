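"""Discrete-event engines for the three training phases.

Training proceeds through lick teaching (learn to drink from the port),
shaping (learn the trial's temporal structure on rewarded trials only),
and the full task.  Each phase is a small state machine executed against
an :class:`~odortrain.agents.Agent`, producing a complete
:class:`~odortrain.core.SessionRecord` (event log plus classified trial
results).

Trial timeline (times relative to trial start, integer ms internally)::

    sample odor [0, odor_duration)
    delay                              (DNMS 4-5 s, DPA 8-9 s; none for GNG)
    test odor / single cue [.., +odor_duration)
    response window                    [offset + w0, offset + w1)
    trial end = window end; next trial starts after the fixed ITI

A lick inside the half-open response window on a go trial is a Hit and
triggers instantaneous reward delivery (pump onset at the triggering
lick's timestamp); on a nogo trial it is a FalseChoice.  No punishment is
ever applied; licks outside the window never change the outcome.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .agents import Agent, TrialContext
from .core import Event, SessionConfig, SessionRecord, TrialResult, TrialSpec, default_config

__all__ = [
    "ContingencyMap",
    "contingency_for",
    "apply_reversal",
    "schedule_trials",
    "classify_response",
    "run_task_session",
    "run_shaping_session",
    "run_lick_teaching_session",
]

# Odorants by task role.  DNMS uses two odors as both sample and test;
# DPA uses two samples and two distinct test odors; GNG uses a single cue.
DNMS_ODORS = ("1-Butanol", "Methyl butyrate")
DPA_SAMPLES = ("1-Butanol", "Methyl butyrate")
DPA_TESTS = ("Hexanoic acid", "Octane")
GNG_GO_CUE = "Hexanoic acid"
GNG_NOGO_CUE = "Octane"

#: lick_off is emitted this many ms after lick_on (log completeness only;
#: classification uses lick onsets).
LICK_PULSE_MS = 30


@dataclass(frozen=True)
class ContingencyMap:
    """Mapping from odor sequence to trial type for one paradigm.

    Keys are ``(sample_odor, test_odor)`` pairs (``test_odor`` is ``None``
    for single-cue GNG); values are ``"go"`` (rewarded if licked) or
    ``"nogo"``.
    """

    paradigm: str
    mapping: dict[tuple[str, Optional[str]], str]

    def trial_type(self, sample: str, test: Optional[str]) -> str:
        return self.mapping[(sample, test)]

    @property
    def sequences(self) -> list[tuple[str, Optional[str]]]:
        return list(self.mapping)

    def go_sequences(self) -> list[tuple[str, Optional[str]]]:
        return [k for k, v in self.mapping.items() if v == "go"]


def contingency_for(paradigm: str) -> ContingencyMap:
    """Build the standard contingency map for a paradigm.

    DNMS rewards non-matched sample/test pairs; DPA rewards the two
    designated sample-test pairings; GNG rewards licking after the Go cue.
    GNG_REV is GNG with the cue-reward relationship reversed.
    """
    if paradigm == "DNMS":
        mapping = {
            (s, t): ("nogo" if s == t else "go")
            for s in DNMS_ODORS
            for t in DNMS_ODORS
        }
    elif paradigm == "DPA":
        paired = {(DPA_SAMPLES[0], DPA_TESTS[0]), (DPA_SAMPLES[1], DPA_TESTS[1])}
        mapping = {
            (s, t): ("go" if (s, t) in paired else "nogo")
            for s in DPA_SAMPLES
            for t in DPA_TESTS
        }
    elif paradigm == "GNG":
        mapping = {(GNG_GO_CUE, None): "go", (GNG_NOGO_CUE, None): "nogo"}
    elif paradigm == "GNG_REV":
        return apply_reversal(contingency_for("GNG"))
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    return ContingencyMap(paradigm, mapping)


def apply_reversal(contingency: ContingencyMap) -> ContingencyMap:
    """Swap go and nogo for every cue of a GNG contingency.

    Reversal is defined only for the single-cue GNG task; applying it
    twice returns the original map.
    """
    if contingency.paradigm not in ("GNG", "GNG_REV"):
        raise ValueError(
            f"reversal is defined only for GNG, not {contingency.paradigm}"
        )
    flipped = {
        k: ("nogo" if v == "go" else "go") for k, v in contingency.mapping.items()
    }
    new_paradigm = "GNG_REV" if contingency.paradigm == "GNG" else "GNG"
    return ContingencyMap(new_paradigm, flipped)


# -- scheduling -------------------------------------------------------------

def _draw_delay_ms(rng: np.random.Generator, delay_range_s: Optional[tuple[float, float]]) -> Optional[int]:
    if delay_range_s is None:
        return None
    lo, hi = delay_range_s
    return int(round(rng.uniform(lo * 1000.0, hi * 1000.0)))


def _block_iter(
    config: SessionConfig,
    contingency: ContingencyMap,
    rng: np.random.Generator,
    go_only: bool,
) -> Iterator[TrialSpec]:
    """Yield trials indefinitely, balanced within blocks of ``block_size``."""
    seqs = contingency.go_sequences() if go_only else contingency.sequences
    if config.block_size % len(seqs):
        raise ValueError(
            f"block_size {config.block_size} not divisible by "
            f"{len(seqs)} sequence types"
        )
    reps = config.block_size // len(seqs)
    index = 0
    while True:
        block = [s for s in seqs for _ in range(reps)]
        rng.shuffle(block)
        for sample, test in block:
            index += 1
            delay_ms = _draw_delay_ms(rng, config.delay_range_s) if test is not None else None
            yield TrialSpec(
                index=index,
                paradigm=config.paradigm,
                sample_odor=sample,
                test_odor=test,
                trial_type=contingency.trial_type(sample, test),
                odor_duration_s=config.odor_duration_s,
                delay_s=None if delay_ms is None else delay_ms / 1000.0,
                response_window_s=config.response_window_s,
                iti_s=config.iti_s,
            )


def schedule_trials(
    paradigm: str,
    n_trials: int,
    seed: int = 0,
    config: Optional[SessionConfig] = None,
    go_only: bool = False,
) -> list[TrialSpec]:
    """Generate a balanced, seeded trial schedule.

    Every consecutive block of ``block_size`` trials contains each odor
    sequence equally often (4 sequence types for DNMS/DPA, 2 for GNG);
    order within a block is a seeded shuffle and per-trial delays are
    drawn uniformly from the paradigm's delay range on the same seed
    stream.  ``n_trials`` must be a positive multiple of the block size.
    """
    if config is None:
        config = default_config(paradigm, phase="shape" if go_only else "task")
    if n_trials <= 0 or n_trials % config.block_size:
        raise ValueError(
            f"n_trials ({n_trials}) must be a positive multiple of "
            f"block_size ({config.block_size})"
        )
    rng = np.random.default_rng(seed)
    it = _block_iter(config, contingency_for(paradigm), rng, go_only)
    return [next(it) for _ in range(n_trials)]


# -- classification ---------------------------------------------------------

def second_odor_offset_s(spec: TrialSpec) -> float:
    """Offset time of the second odor (or single cue), seconds from trial start."""
    if spec.test_odor is None:
        return spec.odor_duration_s
    if spec.delay_s is None:
        raise ValueError("two-odor trial lacks a delay")
    return 2 * spec.odor_duration_s + spec.delay_s


def response_window_rel_trial_s(spec: TrialSpec) -> tuple[float, float]:
    """Half-open response window ``[start, end)`` in seconds from trial start."""
    off = second_odor_offset_s(spec)
    return (off + spec.response_window_s[0], off + spec.response_window_s[1])


def classify_response(spec: TrialSpec, lick_times: Sequence[float]) -> str:
    """Classify a trial from its lick-onset times.

    ``lick_times`` are seconds relative to trial start, sorted ascending.
    A lick inside the half-open response window makes a go trial a Hit
    and a nogo trial a FalseChoice; no in-window lick gives Miss or
    CorrectRejection.  Licks outside the window never change the outcome.
    """
    if any(b < a for a, b in zip(lick_times, lick_times[1:])):
        raise ValueError("lick_times must be sorted ascending")
    w0, w1 = response_window_rel_trial_s(spec)
    licked = any(w0 <= t < w1 for t in lick_times)
    if spec.trial_type == "go":
        return "Hit" if licked else "Miss"
    return "FalseChoice" if licked else "CorrectRejection"


# -- session engine ---------------------------------------------------------

class _Log:
    """Accumulates events; final ordering is a stable sort on timestamp."""

    def __init__(self) -> None:
        self.events: list[Event] = []

    def add(self, t_ms: int, kind: str, **payload) -> None:
        self.events.append(Event(int(t_ms), kind, payload))

    def licks(self, onsets_ms: Sequence[int]) -> None:
        onsets = sorted(set(int(t) for t in onsets_ms))
        for i, on in enumerate(onsets):
            off = on + LICK_PULSE_MS
            if i + 1 < len(onsets):
                off = min(off, onsets[i + 1])
            self.add(on, "lick_on")
            self.add(off, "lick_off")

    def pump(self, t_ms: int, volume_uL: float, trigger: str, **extra) -> None:
        self.add(t_ms, "pump_on", volume_uL=volume_uL, trigger=trigger, **extra)
        self.add(t_ms + 50, "pump_off")

    def sorted_events(self) -> list[Event]:
        return sorted(self.events, key=lambda e: e.t_ms)


def _run_trial(
    log: _Log,
    spec: TrialSpec,
    agent: Agent,
    t0_ms: int,
    phase: str,
    config: SessionConfig,
    mode: Optional[str] = None,
) -> tuple[TrialResult, int]:
    """Execute one trial starting at ``t0_ms``; return (result, next trial start)."""
    od_ms = int(round(spec.odor_duration_s * 1000))
    log.add(t0_ms, "trial_start", trial=spec.index, trial_type=spec.trial_type,
            sample=spec.sample_odor, test=spec.test_odor,
            **({"mode": mode} if mode else {}))
    log.add(t0_ms, "odor_on", odor=spec.sample_odor)
    log.add(t0_ms + od_ms, "odor_off", odor=spec.sample_odor)
    if spec.test_odor is not None:
        delay_ms = int(round((spec.delay_s or 0.0) * 1000))
        t_test = t0_ms + od_ms + delay_ms
        log.add(t_test, "odor_on", odor=spec.test_odor)
        log.add(t_test + od_ms, "odor_off", odor=spec.test_odor)
        offset2 = t_test + od_ms
    else:
        offset2 = t0_ms + od_ms
    w0 = offset2 + int(round(spec.response_window_s[0] * 1000))
    w1 = offset2 + int(round(spec.response_window_s[1] * 1000))
    t_end = w1
    t_next = t_end + int(round(spec.iti_s * 1000))

    ctx = TrialContext(
        index=spec.index,
        paradigm=spec.paradigm,
        phase=phase,
        sample_odor=spec.sample_odor,
        test_odor=spec.test_odor,
        trial_type=spec.trial_type,
        mode=mode,
        t_start_ms=t0_ms,
        window_ms=(w0, w1),
        t_next_ms=t_next,
    )
    raw = agent.decide(ctx)
    licks = sorted(set(int(t) for t in raw if t0_ms <= t < t_next))
    log.licks(licks)

    in_window = [t for t in licks if w0 <= t < w1]
    if spec.trial_type == "go":
        outcome = "Hit" if in_window else "Miss"
    else:
        outcome = "FalseChoice" if in_window else "CorrectRejection"

    reward = 0.0
    if mode == "program_teaching":
        # port advances and water is delivered automatically in the window,
        # regardless of licking
        log.add(w0, "port_forward")
        log.pump(w0, config.reward_uL_per_hit, trigger="auto")
        log.add(t_end, "port_back")
        reward = config.reward_uL_per_hit
    elif outcome == "Hit":
        log.pump(in_window[0], config.reward_uL_per_hit, trigger="lick",
                 lick_t_ms=in_window[0])
        reward = config.reward_uL_per_hit

    log.add(t_end, "trial_end", trial=spec.index, outcome=outcome)
    agent.update(outcome, reward)
    result = TrialResult(
        spec=spec,
        outcome=outcome,
        lick_times_ms=tuple(t - t0_ms for t in licks),
        reward_uL=reward,
        t_start_ms=t0_ms,
        mode=mode,
    )
    return result, t_next


def _finish(
    config: SessionConfig,
    phase: str,
    seed: int,
    log: _Log,
    results: list[TrialResult],
    t_ms: int,
    reason: str,
    partial: bool = False,
    extra_totals: Optional[dict] = None,
) -> SessionRecord:
    log.add(t_ms, "session_end")
    totals = {
        "reward_uL": float(sum(r.reward_uL for r in results)),
        "hits": sum(1 for r in results if r.outcome == "Hit"),
        "trials": len(results),
        "duration_ms": int(t_ms),
    }
    if extra_totals:
        totals.update(extra_totals)
    return SessionRecord(
        config=config,
        phase=phase,
        seed=seed,
        events=log.sorted_events(),
        results=results,
        totals=totals,
        termination_reason=reason,
        partial=partial,
    )


def run_task_session(
    config: SessionConfig,
    agent: Agent,
    seed: Optional[int] = None,
    n_trials: Optional[int] = None,
) -> SessionRecord:
    """Run a full-task session: balanced go and nogo trials, fixed ITI.

    One trial per scheduled :class:`TrialSpec`; Hits trigger reward at the
    first in-window lick.  ``seed`` defaults to ``config.rng_seed`` and
    drives trial order and delay draws.  An exception raised by the agent
    aborts the session with the partial log flagged.
    """
    seed = config.rng_seed if seed is None else seed
    n = config.n_trials if n_trials is None else n_trials
    log = _Log()
    results: list[TrialResult] = []
    t = 0
    if n == 0:
        return _finish(config, "task", seed, log, results, t, "n_trials_complete")
    # no duration cap here: a task session has a fixed, finite trial count,
    # unlike the open-ended shaping/teaching phases
    specs = schedule_trials(config.paradigm, n, seed=seed, config=config)
    reason = "n_trials_complete"
    for spec in specs:
        try:
            result, t = _run_trial(log, spec, agent, t, "task", config)
        except Exception as exc:  # agent failure: flag and stop
            return _finish(config, "task", seed, log, results, t,
                           f"agent_error: {exc}", partial=True)
        results.append(result)
    return _finish(config, "task", seed, log, results, t, reason)


def run_shaping_session(
    config: SessionConfig,
    agent: Agent,
    seed: Optional[int] = None,
) -> SessionRecord:
    """Run a shaping session: rewarded trial types only, adaptive teaching.

    Trials start in *self-learning* mode (reward is lick-triggered).  The
    engine switches to *program-teaching* once the animal has missed
    ``miss_count_trigger`` of the last ``miss_window_trials`` trials
    (sliding window), and stays there until a teaching trial contains an
    in-window lick.  In program-teaching trials the port advances and
    water is delivered automatically in the response window; such a trial
    still counts as a Hit only if an in-window lick occurred, so the
    hit-target accounting reflects the animal's behavior.  The session
    ends when the cumulative Hit count reaches ``daily_hit_target`` (or at
    the safety caps).
    """
    seed = config.rng_seed if seed is None else seed
    log = _Log()
    results: list[TrialResult] = []
    rng = np.random.default_rng(seed)
    trials = _block_iter(config, contingency_for(config.paradigm), rng, go_only=True)
    missed: deque[bool] = deque(maxlen=config.miss_window_trials)
    mode = "self_learning"
    hits = 0
    t = 0
    max_ms = int(config.max_duration_s * 1000)
    reason = "max_trials"
    for spec in trials:
        if hits >= config.daily_hit_target:
            reason = "hit_target"
            break
        if len(results) >= config.max_trials:
            reason = "max_trials"
            break
        if t > max_ms:
            reason = "max_duration"
            break
        try:
            result, t = _run_trial(log, spec, agent, t, "shape", config, mode=mode)
        except Exception as exc:
            return _finish(config, "shape", seed, log, results, t,
                           f"agent_error: {exc}", partial=True)
        results.append(result)
        was_hit = result.outcome == "Hit"
        hits += was_hit
        missed.append(not was_hit)
        if mode == "program_teaching":
            # return to self-learning only after a licked teaching trial
            if was_hit:
                mode = "self_learning"
        elif sum(missed) >= config.miss_count_trigger:
            mode = "program_teaching"
    else:  # pragma: no cover - infinite iterator never exhausts
        pass
    if hits >= config.daily_hit_target:
        reason = "hit_target"
    return _finish(config, "shape", seed, log, results, t, reason,
                   extra_totals={"hit_target": config.daily_hit_target})


def run_lick_teaching_session(
    config: SessionConfig,
    agent: Agent,
    seed: Optional[int] = None,
) -> SessionRecord:
    """Run a lick-teaching session: repeated water-port bouts, no odors.

    Each bout starts with the port advancing and an ``initial_bout_uL``
    delivery; thereafter one ``drop_uL`` drop is delivered for every
    ``licks_per_drop`` licks.  A bout ends after
    ``bout_quiet_timeout_s`` without a lick, or as soon as its cumulative
    volume strictly exceeds ``bout_volume_cap_uL``.  Bouts repeat until
    the session volume reaches ``session_volume_target_uL`` or a safety
    cap (bout count, duration) fires.  Trial results are empty: this
    phase has no trials.
    """
    seed = config.rng_seed if seed is None else seed
    log = _Log()
    t = 0
    session_uL = 0.0
    bout_volumes: list[float] = []
    timeout_ms = int(round(config.bout_quiet_timeout_s * 1000))
    gap_ms = int(round(config.inter_bout_gap_s * 1000))
    max_ms = int(config.max_duration_s * 1000)
    reason = "max_bouts"
    for _bout in range(config.teaching_max_bouts):
        if session_uL >= config.session_volume_target_uL:
            reason = "volume_target"
            break
        if t > max_ms:
            reason = "max_duration"
            break
        bout_start = t
        log.add(bout_start, "port_forward", bout=_bout + 1)
        log.pump(bout_start, config.initial_bout_uL, trigger="auto", bout=_bout + 1)
        bout_uL = config.initial_bout_uL
        try:
            stream = agent.lick_stream(bout_start, max_ms + timeout_ms)
        except Exception as exc:
            log.add(bout_start, "port_back", bout=_bout + 1)
            bout_volumes.append(bout_uL)
            session_uL += bout_uL
            return _finish(
                config, "teach", seed, log, [], bout_start,
                f"agent_error: {exc}", partial=True,
                extra_totals={
                    "reward_uL": float(session_uL),
                    "bout_volumes_uL": bout_volumes,
                    "bouts": len(bout_volumes),
                },
            )
        licks: list[int] = []
        last_t = bout_start
        n_licks = 0
        bout_end = None
        for lt in stream:
            lt = int(lt)
            if lt - last_t > timeout_ms:
                bout_end = last_t + timeout_ms
                break
            licks.append(lt)
            last_t = lt
            n_licks += 1
            if n_licks % config.licks_per_drop == 0:
                bout_uL += config.drop_uL
                log.pump(lt, config.drop_uL, trigger="lick", lick_t_ms=lt,
                         bout=_bout + 1)
                if bout_uL > config.bout_volume_cap_uL:
                    bout_end = lt
                    break
        if bout_end is None:
            bout_end = last_t + timeout_ms
        log.licks(licks)
        log.add(bout_end, "port_back", bout=_bout + 1)
        bout_volumes.append(bout_uL)
        session_uL += bout_uL
        t = bout_end + gap_ms
    if session_uL >= config.session_volume_target_uL:
        reason = "volume_target"
    return _finish(
        config, "teach", seed, log, [], t, reason,
        extra_totals={
            "reward_uL": float(session_uL),
            "bout_volumes_uL": bout_volumes,
            "bouts": len(bout_volumes),
        },
    )
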