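"""Domain types and configuration for olfactory-task training sessions.

The package simulates an automatic training rig for head-fixed mice
performing odor-guided tasks: delayed non-match to sample (DNMS), delayed
paired association (DPA), Go/No-go (GNG), and GNG with reversed cue-reward
contingency (GNG_REV).  Everything downstream -- the protocol state
machines, the simulated mouse agents, the behavioral statistics -- shares
the types defined here.

Time is kept as integer milliseconds from session start everywhere inside
the engine (mirroring microcontroller-style event timestamps and avoiding
float ordering artifacts); configuration files and analysis outputs use
seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional

__all__ = [
    "PARADIGMS",
    "EVENT_KINDS",
    "Event",
    "TrialSpec",
    "TrialResult",
    "SessionConfig",
    "SessionRecord",
    "default_config",
    "validate_event_log",
]

PARADIGMS = ("DNMS", "DPA", "GNG", "GNG_REV")

#: Trial phases a config can target: lick teaching, shaping, or the full task.
PHASES = ("teach", "shape", "task")

EVENT_KINDS = frozenset(
    {
        "lick_on",
        "lick_off",
        "odor_on",
        "odor_off",
        "pump_on",
        "pump_off",
        "port_forward",
        "port_back",
        "trial_start",
        "trial_end",
        "session_end",
    }
)

GO_OUTCOMES = ("Hit", "Miss")
NOGO_OUTCOMES = ("FalseChoice", "CorrectRejection")
OUTCOMES = GO_OUTCOMES + NOGO_OUTCOMES


@dataclass(frozen=True)
class Event:
    """One timestamped rig/behavior occurrence.

    Parameters
    ----------
    t_ms : int
        Milliseconds from session start (>= 0).
    kind : str
        One of :data:`EVENT_KINDS` (lick on/off, odor valve on/off,
        peristaltic pump on/off, port movement, trial markers).
    payload : dict
        Optional details: odor identity, trial index, volume in uL,
        reward trigger provenance.
    """

    t_ms: int
    kind: str
    payload: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"t_ms": self.t_ms, "event": self.kind}
        d.update(self.payload)
        return d


@dataclass(frozen=True)
class TrialSpec:
    """One trial's paradigm, odor sequence, timing, and contingency.

    ``trial_type`` is "go" for rewarded-if-licked trials (non-matched pair
    for DNMS, designated pair for DPA, Go cue for GNG) and "nogo"
    otherwise.  ``response_window_s`` is a half-open ``[start, end)``
    interval in seconds relative to the offset of the second odor (the
    single cue's offset for GNG).
    """

    index: int
    paradigm: str
    sample_odor: str
    test_odor: Optional[str]
    trial_type: str
    odor_duration_s: float
    delay_s: Optional[float]
    response_window_s: tuple[float, float]
    iti_s: float

    def __post_init__(self) -> None:
        if self.trial_type not in ("go", "nogo"):
            raise ValueError(f"trial_type must be 'go' or 'nogo', got {self.trial_type!r}")
        lo, hi = self.response_window_s
        if not lo < hi:
            raise ValueError("response window start must precede end")


@dataclass(frozen=True)
class TrialResult:
    """Classified outcome of one executed trial.

    ``lick_times_ms`` are milliseconds relative to trial start, covering
    every lick from trial start up to (but excluding) the next trial's
    start.  ``outcome`` is Hit/Miss on go trials and
    FalseChoice/CorrectRejection on nogo trials.  ``mode`` distinguishes
    shaping-phase self-learning from program-teaching trials (``None``
    outside shaping).
    """

    spec: TrialSpec
    outcome: str
    lick_times_ms: tuple[int, ...]
    reward_uL: float
    t_start_ms: int
    mode: Optional[str] = None

    def __post_init__(self) -> None:
        if self.spec.trial_type == "go" and self.outcome not in GO_OUTCOMES:
            raise ValueError(f"go trial cannot end as {self.outcome}")
        if self.spec.trial_type == "nogo" and self.outcome not in NOGO_OUTCOMES:
            raise ValueError(f"nogo trial cannot end as {self.outcome}")

    @property
    def lick_times_s(self) -> tuple[float, ...]:
        return tuple(t / 1000.0 for t in self.lick_times_ms)

    @property
    def correct(self) -> bool:
        return self.outcome in ("Hit", "CorrectRejection")


# Per-paradigm defaults: inter-trial interval, delay range between the two
# odors, and the response window relative to second-odor offset.
_PARADIGM_DEFAULTS: dict[str, dict[str, Any]] = {
    "DNMS": {"iti_s": 10.0, "delay_range_s": (4.0, 5.0), "response_window_s": (0.5, 1.5)},
    "DPA": {"iti_s": 16.0, "delay_range_s": (8.0, 9.0), "response_window_s": (0.5, 1.0)},
    "GNG": {"iti_s": 5.0, "delay_range_s": None, "response_window_s": (0.5, 1.5)},
    "GNG_REV": {"iti_s": 5.0, "delay_range_s": None, "response_window_s": (0.5, 1.5)},
}

#: Response window used by the shaping phase for every paradigm (0.5-1.5 s
#: after second-odor offset); the full DPA task narrows it to 0.5-1.0 s.
_SHAPING_WINDOW_S = (0.5, 1.5)


@dataclass
class SessionConfig:
    """All protocol parameters for one training session.

    Defaults are the standard operating values of the training system:
    1 s odor pulses; paradigm-specific ITIs (10 s DNMS, 16 s DPA, 5 s GNG)
    and delays (4-5 s DNMS, 8-9 s DPA); ~5 uL water per rewarded trial;
    24-trial blocks; 80% criterion over a 24-trial sliding window, three
    consecutive qualifying windows for "well trained".

    Lick-teaching parameters: each bout opens with a 10 uL delivery and
    the port moving to the mouth, then 4 uL per three licks; a bout ends
    after 2 s without licking or once its volume exceeds 200 uL; the
    session ends once 400 uL have been delivered in total.

    Shaping parameters: switch from self-learning to program-teaching
    after 5 misses within the last 30 trials (sliding); the day ends at
    100 hit trials.
    """

    paradigm: str = "DNMS"
    odor_duration_s: float = 1.0
    delay_range_s: Optional[tuple[float, float]] = (4.0, 5.0)
    response_window_s: tuple[float, float] = (0.5, 1.5)
    iti_s: float = 10.0
    reward_uL_per_hit: float = 5.0
    block_size: int = 24
    n_trials: int = 120
    criterion_rate: float = 0.80
    criterion_window: int = 24
    criterion_consecutive: int = 3
    # lick-teaching phase
    initial_bout_uL: float = 10.0
    drop_uL: float = 4.0
    licks_per_drop: int = 3
    bout_quiet_timeout_s: float = 2.0
    bout_volume_cap_uL: float = 200.0
    session_volume_target_uL: float = 400.0
    teaching_max_bouts: int = 100
    inter_bout_gap_s: float = 5.0
    # shaping phase
    miss_count_trigger: int = 5
    miss_window_trials: int = 30
    daily_hit_target: int = 100
    # safety caps: sessions last 1-2 h on the rig; pathological agents must
    # not run forever
    max_trials: int = 1000
    max_duration_s: float = 7200.0
    pump_pulse_ms: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(
                f"unknown paradigm {self.paradigm!r}; valid options: {', '.join(PARADIGMS)}"
            )
        for name in (
            "odor_duration_s",
            "iti_s",
            "bout_quiet_timeout_s",
            "max_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.criterion_rate < 1:
            raise ValueError("criterion_rate must lie strictly between 0 and 1")
        lo, hi = self.response_window_s
        if not lo < hi:
            raise ValueError("response_window_s start must precede end")
        if self.delay_range_s is not None:
            dlo, dhi = self.delay_range_s
            if not 0 < dlo <= dhi:
                raise ValueError("delay_range_s must satisfy 0 < low <= high")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        n_types = 4 if self.paradigm in ("DNMS", "DPA") else 2
        if self.block_size % n_types:
            raise ValueError(
                f"block_size {self.block_size} not divisible by the "
                f"{n_types} odor-sequence types of {self.paradigm}"
            )
        if self.licks_per_drop < 1:
            raise ValueError("licks_per_drop must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("delay_range_s", "response_window_s"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("delay_range_s", "response_window_s"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def default_config(paradigm: str, phase: str = "task", **overrides: Any) -> SessionConfig:
    """Return the standard configuration for a paradigm and training phase.

    Parameters
    ----------
    paradigm : {"DNMS", "DPA", "GNG", "GNG_REV"}
    phase : {"task", "shape", "teach"}
        The shaping phase uses the wider 0.5-1.5 s response window for all
        paradigms; the full task narrows DPA's window to 0.5-1.0 s.
    **overrides
        Field-by-field overrides applied after the defaults.
    """
    if paradigm not in PARADIGMS:
        raise ValueError(
            f"unknown paradigm {paradigm!r}; valid options: {', '.join(PARADIGMS)}"
        )
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; valid options: {', '.join(PHASES)}")
    kwargs: dict[str, Any] = {"paradigm": paradigm}
    kwargs.update(_PARADIGM_DEFAULTS[paradigm])
    if phase == "shape":
        kwargs["response_window_s"] = _SHAPING_WINDOW_S
    kwargs.update(overrides)
    return SessionConfig(**kwargs)


@dataclass
class SessionRecord:
    """Complete record of one simulated session.

    Holds the configuration snapshot, the full event log, the per-trial
    results, and session totals.  Totals are redundant with the log and
    results by construction (conservation is asserted by the test suite,
    not enforced here).
    """

    config: SessionConfig
    phase: str
    seed: int
    events: list[Event]
    results: list[TrialResult]
    totals: dict = field(default_factory=dict)
    termination_reason: str = ""
    partial: bool = False

    @property
    def outcome_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in OUTCOMES}
        for r in self.results:
            counts[r.outcome] += 1
        return counts

    @property
    def total_reward_uL(self) -> float:
        return float(self.totals.get("reward_uL", 0.0))


def validate_event_log(events: list[Event]) -> list[str]:
    """Check an event log against the engine's structural invariants.

    Returns a list of human-readable violations (empty iff the log is
    valid); never raises.  Checked rules:

    * timestamps are non-negative and non-decreasing;
    * every ``lick_on`` is eventually followed by a ``lick_off`` and
      ``lick_off`` never arrives without a pending ``lick_on``;
    * ``odor_on``/``odor_off`` strictly alternate per odor line;
    * event kinds belong to the known vocabulary.
    """
    violations: list[str] = []
    prev_t: Optional[int] = None
    lick_open: Optional[int] = None
    odor_open: dict[Any, int] = {}
    for i, ev in enumerate(events):
        if ev.kind not in EVENT_KINDS:
            violations.append(f"event {i}: unknown kind {ev.kind!r}")
        if ev.t_ms < 0:
            violations.append(f"event {i}: negative timestamp {ev.t_ms}")
        if prev_t is not None and ev.t_ms < prev_t:
            violations.append(
                f"event {i}: non-monotone timestamp ({ev.t_ms} < {prev_t})"
            )
        prev_t = ev.t_ms
        if ev.kind == "lick_on":
            if lick_open is not None:
                violations.append(
                    f"event {i}: unterminated lick (lick_on at event {lick_open} "
                    "never closed)"
                )
            lick_open = i
        elif ev.kind == "lick_off":
            if lick_open is None:
                violations.append(f"event {i}: lick_off without matching lick_on")
            lick_open = None
        elif ev.kind in ("odor_on", "odor_off"):
            line = ev.payload.get("odor")
            opened = odor_open.get(line)
            if ev.kind == "odor_on":
                if opened is not None:
                    violations.append(
                        f"event {i}: odor_on for line {line!r} while already open "
                        f"(event {opened})"
                    )
                odor_open[line] = i
            else:
                if opened is None:
                    violations.append(
                        f"event {i}: odor_off for line {line!r} without odor_on"
                    )
                odor_open.pop(line, None)
    if lick_open is not None:
        violations.append(f"event {lick_open}: unterminated lick at end of log")
    for line, idx in odor_open.items():
        violations.append(f"event {idx}: odor line {line!r} left open at end of log")
    return violations
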