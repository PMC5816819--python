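"""Simulated mouse policies.

The protocol engines in :mod:`odortrain.protocols` are written against
live animals in the real rig; here an :class:`Agent` stands in for the
mouse.  An agent maps trial context (odor sequence observed, phase,
timing) to a lick schedule, and may update internal state from the
outcome and reward of each trial.

The policies are engineering stand-ins, not behavioral models fitted to
real mice: ``silent`` and ``continuous_licker`` exercise protocol edge
cases, ``bernoulli`` gives calibrated stochastic performance, and
``delta_rule_learner`` is a minimal Rescorla-Wagner learner whose
simulated learning curves qualitatively resemble task acquisition
(rising performance and correct-rejection rate, ceiling hit rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "TrialContext",
    "Agent",
    "SilentAgent",
    "ContinuousLicker",
    "BernoulliAgent",
    "DeltaRuleLearner",
    "silent_agent",
    "continuous_licker",
    "bernoulli_agent",
    "delta_rule_learner",
    "make_agent",
]


@dataclass(frozen=True)
class TrialContext:
    """What an agent observes before deciding its licks for a trial.

    All times are absolute milliseconds from session start.  The window
    is half-open ``[start, end)``.  ``t_next_ms`` is the start of the next
    trial (trial end plus ITI); licks may be scheduled anywhere in
    ``[t_start_ms, t_next_ms)``.
    """

    index: int
    paradigm: str
    phase: str
    sample_odor: str
    test_odor: Optional[str]
    trial_type: str
    mode: Optional[str]
    t_start_ms: int
    window_ms: tuple[int, int]
    t_next_ms: int

    @property
    def sequence(self) -> tuple[str, ...]:
        if self.test_odor is None:
            return (self.sample_odor,)
        return (self.sample_odor, self.test_odor)

    @property
    def window_mid_ms(self) -> int:
        return (self.window_ms[0] + self.window_ms[1]) // 2


class Agent:
    """Base policy: decide licks per trial, update state from feedback.

    ``decide`` returns absolute lick-onset times (ms) within
    ``[ctx.t_start_ms, ctx.t_next_ms)``; ``update`` is the only state
    mutation and receives the classified outcome and the reward actually
    delivered.  ``lick_stream`` supplies licking over an arbitrary time
    span for trial-free phases (lick teaching); by default agents do not
    lick outside trials.
    """

    name = "agent"

    def decide(self, ctx: TrialContext) -> list[int]:
        raise NotImplementedError

    def update(self, outcome: str, reward_uL: float) -> None:  # noqa: B027
        pass

    def lick_stream(self, t0_ms: int, t1_ms: int) -> list[int]:
        return []

    def get_params(self) -> dict:
        return {}


class SilentAgent(Agent):
    """Never licks.  Every go trial is a Miss, every nogo a CorrectRejection."""

    name = "silent"

    def decide(self, ctx: TrialContext) -> list[int]:
        return []


class ContinuousLicker(Agent):
    """Licks metronomically at ``rate_hz`` for the whole session, ITIs included.

    Lick onsets sit on the absolute grid of multiples of the inter-lick
    interval, so spacing is exact across trial boundaries.  Any response
    window at least one interval long is guaranteed a lick.
    """

    name = "continuous"

    def __init__(self, rate_hz: float = 8.0):
        if rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.rate_hz = float(rate_hz)
        self.interval_ms = max(1, round(1000.0 / rate_hz))

    def _grid(self, t0_ms: int, t1_ms: int) -> list[int]:
        first = -(-t0_ms // self.interval_ms) * self.interval_ms  # ceil to grid
        return list(range(first, t1_ms, self.interval_ms))

    def decide(self, ctx: TrialContext) -> list[int]:
        return self._grid(ctx.t_start_ms, ctx.t_next_ms)

    def lick_stream(self, t0_ms: int, t1_ms: int) -> list[int]:
        return self._grid(t0_ms, t1_ms)

    def get_params(self) -> dict:
        return {"rate_hz": self.rate_hz}


class BernoulliAgent(Agent):
    """Licks once mid-window with a per-trial-type probability.

    ``p_lick_by_type`` maps ``"go"``/``"nogo"`` to lick probabilities.
    ``p(go)=1, p(nogo)=0`` is a perfect performer; equal probabilities
    give chance performance.
    """

    name = "bernoulli"

    def __init__(self, p_lick_by_type: dict[str, float], seed: int = 0):
        for k, p in p_lick_by_type.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_lick_by_type[{k!r}]={p} outside [0, 1]")
        self.p_lick_by_type = dict(p_lick_by_type)
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)

    def decide(self, ctx: TrialContext) -> list[int]:
        p = self.p_lick_by_type.get(ctx.trial_type, 0.0)
        if p > 0 and self._rng.random() < p:
            return [ctx.window_mid_ms]
        return []

    def get_params(self) -> dict:
        return {"p_lick_by_type": dict(self.p_lick_by_type), "seed": self.seed}


def perfect_agent() -> BernoulliAgent:
    """Agent that licks on every go trial and never on nogo trials."""
    return BernoulliAgent({"go": 1.0, "nogo": 0.0})


class DeltaRuleLearner(Agent):
    """Rescorla-Wagner learner over odor sequences, gated on responding.

    Maintains a value estimate ``V(sequence)`` initialized at ``p0`` and
    licks (once, mid-window) with probability ``V``.  After a licked
    trial, ``V <- V + alpha * (r - V)`` with ``r = 1`` if reward was
    delivered and 0 otherwise.  Trials without a lick leave ``V``
    unchanged: the task gives no feedback on withheld licks (there is no
    punishment), so learning only on responded trials is the minimal
    consistent update.
    """

    name = "delta"

    def __init__(self, alpha: float = 0.1, p0: float = 0.6, seed: int = 0):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 < p0 < 1.0:
            raise ValueError("p0 must lie in (0, 1)")
        self.alpha = float(alpha)
        self.p0 = float(p0)
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)
        self.V: dict[tuple[str, ...], float] = {}
        self._last_seq: Optional[tuple[str, ...]] = None
        self._last_licked: bool = False

    def decide(self, ctx: TrialContext) -> list[int]:
        seq = ctx.sequence
        v = self.V.setdefault(seq, self.p0)
        self._last_seq = seq
        self._last_licked = self._rng.random() < v
        return [ctx.window_mid_ms] if self._last_licked else []

    def update(self, outcome: str, reward_uL: float) -> None:
        if self._last_seq is None or not self._last_licked:
            return
        r = 1.0 if reward_uL > 0 else 0.0
        v = self.V[self._last_seq]
        self.V[self._last_seq] = v + self.alpha * (r - v)

    def get_params(self) -> dict:
        return {"alpha": self.alpha, "p0": self.p0, "seed": self.seed}


# -- factory functions ------------------------------------------------------

def silent_agent() -> SilentAgent:
    return SilentAgent()


def continuous_licker(rate_hz: float = 8.0) -> ContinuousLicker:
    return ContinuousLicker(rate_hz)


def bernoulli_agent(p_lick_by_type: dict[str, float], seed: int = 0) -> BernoulliAgent:
    return BernoulliAgent(p_lick_by_type, seed)


def delta_rule_learner(alpha: float = 0.1, p0: float = 0.6, seed: int = 0) -> DeltaRuleLearner:
    return DeltaRuleLearner(alpha, p0, seed)


_REGISTRY = {
    "silent": silent_agent,
    "continuous": continuous_licker,
    "bernoulli": bernoulli_agent,
    "delta": delta_rule_learner,
    "perfect": perfect_agent,
}


def make_agent(name: str, **params) -> Agent:
    """Construct an agent by registry name (for the CLI and config files)."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown agent {name!r}; valid options: {', '.join(sorted(_REGISTRY))}"
        ) from None
    return factory(**params)
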