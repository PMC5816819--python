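"""Behavioral statistics on trial results and event logs.

Implements the standard signal-detection bookkeeping for lick-based
go/nogo-style tasks:

* per-block counts, performance ``(hits + correct rejections) / total``,
  hit / false-choice / correct-rejection rates;
* discriminability ``d' = norminv(hit rate) - norminv(false-choice
  rate)``, with extreme rates clipped to ``1/(2n)`` and ``1 - 1/(2n)``
  (``n`` = the number of possible hit or false-choice trials on that
  side) so the normal quantile stays finite;
* licking efficiency (fraction of licks that triggered a reward);
* trial-aligned lick-rate curves (100 ms bins, span-5 moving-average
  smoothing with symmetrically shrinking windows at the edges);
* trials-to-criterion and the well-trained test (sliding 24-trial
  windows, correct rate strictly above 80%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import Event, SessionRecord, TrialResult

__all__ = [
    "BlockStats",
    "LickRateCurve",
    "CriterionResult",
    "block_stats",
    "block_stats_frame",
    "clipped_rate",
    "dprime",
    "licking_efficiency",
    "licking_rate",
    "trials_to_criterion",
    "is_well_trained",
]


@dataclass(frozen=True)
class BlockStats:
    """Counts and derived rates for one block of trials."""

    block_index: int
    hit: int
    miss: int
    false_choice: int
    correct_rejection: int
    complete: bool

    @property
    def n_trials(self) -> int:
        return self.hit + self.miss + self.false_choice + self.correct_rejection

    @property
    def n_go(self) -> int:
        return self.hit + self.miss

    @property
    def n_nogo(self) -> int:
        return self.false_choice + self.correct_rejection

    @property
    def performance(self) -> float:
        return (self.hit + self.correct_rejection) / self.n_trials

    @property
    def hit_rate(self) -> Optional[float]:
        return self.hit / self.n_go if self.n_go else None

    @property
    def false_choice_rate(self) -> Optional[float]:
        return self.false_choice / self.n_nogo if self.n_nogo else None

    @property
    def cr_rate(self) -> Optional[float]:
        return self.correct_rejection / self.n_nogo if self.n_nogo else None

    @property
    def d_prime(self) -> Optional[float]:
        if not (self.n_go and self.n_nogo):
            return None
        return dprime(self.hit, self.n_go, self.false_choice, self.n_nogo)


def _outcomes(results: Sequence[Union[TrialResult, str]]) -> list[str]:
    return [r.outcome if isinstance(r, TrialResult) else r for r in results]


def block_stats(
    results: Sequence[Union[TrialResult, str]], block_size: int = 24
) -> list[BlockStats]:
    """Bin trial results into consecutive blocks and compute rates.

    An incomplete trailing block is reported with ``complete=False``.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    outcomes = _outcomes(results)
    if not outcomes:
        raise ValueError("results must be nonempty")
    blocks = []
    for b in range(0, len(outcomes), block_size):
        chunk = outcomes[b : b + block_size]
        blocks.append(
            BlockStats(
                block_index=b // block_size + 1,
                hit=chunk.count("Hit"),
                miss=chunk.count("Miss"),
                false_choice=chunk.count("FalseChoice"),
                correct_rejection=chunk.count("CorrectRejection"),
                complete=len(chunk) == block_size,
            )
        )
    return blocks


def block_stats_frame(
    results: Sequence[Union[TrialResult, str]], block_size: int = 24
) -> pd.DataFrame:
    """Per-block statistics as a tidy DataFrame (one row per block)."""
    rows = []
    for s in block_stats(results, block_size):
        rows.append(
            {
                "block_index": s.block_index,
                "hit": s.hit,
                "miss": s.miss,
                "false_choice": s.false_choice,
                "correct_rejection": s.correct_rejection,
                "n_trials": s.n_trials,
                "performance": s.performance,
                "hit_rate": s.hit_rate,
                "false_choice_rate": s.false_choice_rate,
                "cr_rate": s.cr_rate,
                "d_prime": s.d_prime,
                "complete": s.complete,
            }
        )
    return pd.DataFrame(rows)


def clipped_rate(k_successes: int, n_possible: int) -> float:
    """Rate ``k/n`` with extremes clipped away from 0 and 1.

    A rate of exactly 0 is replaced by ``1/(2n)`` and a rate of exactly 1
    by ``1 - 1/(2n)``, so the normal quantile in ``d'`` stays finite.
    """
    if n_possible < 1:
        raise ValueError("rate undefined: no possible trials (n = 0)")
    if not 0 <= k_successes <= n_possible:
        raise ValueError("k_successes must lie in [0, n_possible]")
    if k_successes == 0:
        return 1.0 / (2 * n_possible)
    if k_successes == n_possible:
        return 1.0 - 1.0 / (2 * n_possible)
    return k_successes / n_possible


def dprime(hit_k: int, hit_n: int, fc_k: int, fc_n: int) -> float:
    """Discriminability index from hit and false-choice counts.

    ``d' = norminv(hit rate) - norminv(false-choice rate)`` where
    ``norminv`` is the standard-normal quantile and both rates are
    clipped via :func:`clipped_rate` (each side uses its own ``n``).
    """
    h = clipped_rate(hit_k, hit_n)
    f = clipped_rate(fc_k, fc_n)
    return float(norm.ppf(h) - norm.ppf(f))


def licking_efficiency(source: Union[SessionRecord, Sequence[Event]]) -> float:
    """Fraction of licks that triggered a water reward.

    ``rewarded licks / (rewarded + unrewarded licks)``.  A lick is
    rewarded iff its timestamp triggered a pump onset (the pump event
    carries the triggering lick's timestamp).  Raises if the log contains
    no licks -- the ratio is undefined, not zero.
    """
    events = source.events if isinstance(source, SessionRecord) else list(source)
    lick_times = [e.t_ms for e in events if e.kind == "lick_on"]
    if not lick_times:
        raise ValueError("licking efficiency undefined: no licks in log")
    rewarded_ts = {
        e.payload["lick_t_ms"]
        for e in events
        if e.kind == "pump_on" and e.payload.get("trigger") == "lick"
    }
    rewarded = sum(1 for t in lick_times if t in rewarded_ts)
    return rewarded / len(lick_times)


def smooth_moving_average(y: Sequence[float], span: int = 5) -> np.ndarray:
    """Centered moving average with symmetric window shrink at the edges.

    Interior points average ``span`` neighbors; near the boundaries the
    window shrinks symmetrically (spans 1, 3, 5, ..., 5, 3, 1), so a
    constant series is left unchanged everywhere.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be a positive odd integer")
    y = np.asarray(y, dtype=float)
    half = span // 2
    out = np.empty_like(y)
    n = len(y)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = y[i - h : i + h + 1].mean()
    return out


@dataclass(frozen=True)
class LickRateCurve:
    """Trial-averaged lick rate: raw and smoothed, in Hz per 100 ms bin."""

    bin_edges_s: np.ndarray  # length n_bins + 1, aligned to trial start
    rate_hz: np.ndarray
    smoothed_hz: np.ndarray

    @property
    def bin_centers_s(self) -> np.ndarray:
        return (self.bin_edges_s[:-1] + self.bin_edges_s[1:]) / 2.0


def licking_rate(
    lick_times_by_trial: Sequence[Sequence[float]],
    duration_s: float,
    bin_ms: float = 100.0,
    span: int = 5,
) -> LickRateCurve:
    """Trial-aligned lick-rate curve.

    ``lick_times_by_trial`` holds, per trial, lick-onset times in seconds
    relative to trial start.  Counts are binned at ``bin_ms``, averaged
    across trials, converted to Hz, and smoothed by a span-``span``
    centered moving average.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    if span % 2 == 0 or span < 1:
        raise ValueError("span must be a positive odd integer")
    n_trials = len(lick_times_by_trial)
    if n_trials == 0:
        raise ValueError("need at least one trial")
    bin_s = bin_ms / 1000.0
    n_bins = max(1, int(np.ceil(duration_s / bin_s)))
    edges = np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    for licks in lick_times_by_trial:
        if len(licks):
            hist, _ = np.histogram(licks, bins=edges)
            counts += hist
    rate = counts / n_trials / bin_s
    return LickRateCurve(
        bin_edges_s=edges,
        rate_hz=rate,
        smoothed_hz=smooth_moving_average(rate, span),
    )


@dataclass(frozen=True)
class CriterionResult:
    """Trials to criterion (``None`` means not reaching criterion, NRC)."""

    trials_to_criterion: Optional[int]
    well_trained: bool

    @property
    def nrc(self) -> bool:
        return self.trials_to_criterion is None


def _correct_sequence(outcomes: Sequence[Union[TrialResult, str, bool]]) -> np.ndarray:
    vals = []
    for o in outcomes:
        if isinstance(o, TrialResult):
            vals.append(o.correct)
        elif isinstance(o, str):
            vals.append(o in ("Hit", "CorrectRejection"))
        else:
            vals.append(bool(o))
    return np.asarray(vals, dtype=float)


def _window_rates(correct: np.ndarray, window: int) -> np.ndarray:
    if len(correct) < window:
        return np.empty(0)
    c = np.concatenate([[0.0], np.cumsum(correct)])
    return (c[window:] - c[:-window]) / window


def trials_to_criterion(
    outcomes: Sequence[Union[TrialResult, str, bool]],
    rate: float = 0.80,
    window: int = 24,
    consecutive: int = 3,
) -> CriterionResult:
    """Ordinal of the trial completing the first criterion window.

    Scans sliding windows of ``window`` consecutive trials (stride 1) and
    returns the 1-based index of the final trial of the first window
    whose correct fraction is strictly greater than ``rate`` (so the
    minimum possible value is ``window``); ``None`` (NRC) if no window
    qualifies.  ``well_trained`` additionally requires ``consecutive``
    qualifying windows in a row.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    correct = _correct_sequence(outcomes)
    rates = _window_rates(correct, window)
    qualifying = rates > rate
    idx = np.flatnonzero(qualifying)
    ttc = int(idx[0]) + window if idx.size else None
    well = _has_consecutive(qualifying, consecutive)
    return CriterionResult(trials_to_criterion=ttc, well_trained=well)


def _has_consecutive(flags: np.ndarray, k: int) -> bool:
    run = 0
    for f in flags:
        run = run + 1 if f else 0
        if run >= k:
            return True
    return False


def is_well_trained(
    outcomes: Sequence[Union[TrialResult, str, bool]],
    rate: float = 0.80,
    window: int = 24,
    consecutive: int = 3,
) -> bool:
    """True iff ``consecutive`` successive sliding windows each exceed ``rate``.

    Windows advance one trial at a time; "exceed" is strict (a window at
    exactly the criterion rate does not qualify).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    correct = _correct_sequence(outcomes)
    return _has_consecutive(_window_rates(correct, window) > rate, consecutive)
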