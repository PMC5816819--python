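# Methods

## Scope and model of the rig

`odortrain` reproduces, in software, the discrete-event behavior of an
automatic training rig for head-fixed mice performing odor-guided
tasks. The simulation covers everything the rig's controller decides —
trial scheduling, valve and pump timing, reward contingencies, the
adaptive teaching/shaping logic, and session termination — and replaces
the two physical parts, the animal and the hardware, with (a) pluggable
agent policies that emit lick times and (b) an idealized event log in
integer milliseconds. Hardware transduction (valve pneumatics, pump
calibration, capacitive lick detection) is out of scope except for the
kinetic model of delivered odor concentration described below.

## Trial structure and classification

A trial is: sample odor (1 s), a delay drawn uniformly per trial from
the paradigm's range (DNMS 4–5 s, DPA 8–9 s; rounded to the
millisecond), test odor (1 s), then a response window defined relative
to second-odor offset. GNG omits the delay and second odor. The window
is **half-open** `[start, end)`: a lick exactly at the start counts,
one exactly at the end does not. Half-open intervals compose without
double counting; the rig's own documentation states the window bounds
without boundary semantics, so this is a package convention, applied
identically in the engine and in `classify_response`.

Outcomes follow signal-detection bookkeeping: go + in-window lick →
Hit (reward delivered at the triggering lick's timestamp, i.e. with
zero latency); go + no lick → Miss; nogo + lick → FalseChoice; nogo +
no lick → CorrectRejection. No punishment exists anywhere in the
protocol, and licks outside the window never affect classification.

Trials are scheduled in balanced blocks of 24 (each of the 4 odor
sequences of DNMS/DPA, or 2 cues of GNG, appears equally often; order
is a seeded within-block shuffle). 24 is divisible by both 4 and 2, so
block statistics are comparable across paradigms.

## Training phases

**Lick teaching** has no trials. Each bout: the port advances and
delivers 10 μL; thereafter 4 μL per 3 licks; the bout ends after 2 s
without a lick or as soon as its volume strictly exceeds 200 μL; the
session ends once 400 μL total are delivered. With a continuous licker
the arithmetic is exact: a bout terminates at 10 + 4·48 = 202 μL, and
the session after two bouts at 404 μL.

**Shaping** schedules only rewarded (go) trial types. Two trial modes
alternate automatically: *self-learning* (reward is lick-triggered) and
*program-teaching* (port advances, reward is delivered automatically in
the window). The engine switches to program-teaching when 5 of the
last 30 trials were misses (a sliding window over trials of both modes,
not reset on mode switches — the simplest formal reading of the rule)
and returns to self-learning after a teaching trial containing an
in-window lick. An automatically delivered reward is logged as reward,
but the trial counts as a **Hit only if an in-window lick occurred**,
so the 100-hit daily termination target reflects the animal's behavior
rather than the machine's generosity.

**Full task** runs exactly the requested trial count. Safety caps
(1000 trials, 2 h simulated) apply only to the open-ended shaping and
teaching phases, which a pathological agent could otherwise keep alive
forever; a task session is finite by construction.

## Key parameters (all in `SessionConfig`)

| parameter | default | unit | note |
|---|---|---|---|
| `odor_duration_s` | 1 | s | per odor pulse |
| `delay_range_s` | DNMS [4,5]; DPA [8,9] | s | uniform per trial, seeded |
| `response_window_s` | [0.5,1.5]; DPA task [0.5,1.0] | s | re: second-odor offset; shaping uses [0.5,1.5] everywhere |
| `iti_s` | DNMS 10; DPA 16; GNG 5 | s | fixed |
| `reward_uL_per_hit` | 5 | μL | one pump pulse per Hit |
| `block_size` | 24 | trials | balanced within block |
| `criterion_rate/window/consecutive` | 0.80 / 24 / 3 | — | strict ">", stride-1 sliding |
| `initial_bout_uL` / `drop_uL` / `licks_per_drop` | 10 / 4 / 3 | μL, licks | teaching drop schedule |
| `bout_quiet_timeout_s` / `bout_volume_cap_uL` | 2 / 200 | s, μL | cap comparison is strict ">" |
| `session_volume_target_uL` | 400 | μL | teaching termination |
| `miss_count_trigger` / `miss_window_trials` | 5 / 30 | trials | 35-trial variant selectable |
| `daily_hit_target` | 100 | hits | shaping termination |

Two parameters have documented variants (a ~5 μL drop and a 35-trial
miss window); the defaults above follow the flow-chart values, and the
variants are plain config overrides, never hard-coded.

## Agents: what they emulate and what they do not

Agents map trial context to lick times; `update(outcome, reward)` is
their only state mutation, and every agent is deterministic given its
seed. `silent` and `continuous_licker` (default 8 Hz, within the
typical 6–9 Hz rodent licking range; any rate above one lick per window
works) bound the protocol's behavior and exercise termination rules.
`bernoulli_agent` produces calibrated chance or perfect performance.
`delta_rule_learner` is a Rescorla–Wagner learner over odor sequences:
it licks with probability `V(sequence)` (initialized at `p0 = 0.6`) and
updates `V ← V + α(r − V)` only after licked trials, because the task
gives no feedback on withheld licks. With `α = 0.1` over 600 DNMS
trials it reproduces the qualitative learning-curve shape — rising
performance and correct-rejection rate with a ceiling hit rate — and
after a GNG reversal its performance collapses and then recovers above
the 80% criterion, because the decayed value of the new go cue must be
re-inflated through occasional exploratory licks.

None of this is a fitted behavioral model: there is no satiety,
motivation, sniffing, timing jitter, or inter-day memory. Passing
tests demonstrate that the *protocol logic and statistics* are correct
and internally consistent, not that real mice behave like these
policies.

## Olfactometer kinetics

Delivered relative concentration is a single exponential per phase,
calibrated per odorant from two measured constants: rising latency
`L95` (time to 95% of plateau, giving `τ_r = L95 / ln 20`) and decay
constant `τ_d` (time to 1/e after valve closing). The bundled library
covers the four task odorants (L95/τ_d in ms: 1-Butanol 18/20, Methyl
butyrate 17/22, Hexanoic acid 31/41, Octane 71/31). The plateau is
normalized to 1 — detector readouts are relative, so the vapor ratio is
metadata only — and traces repeat exactly across valve cycles (no
adaptation or residual-odor term, neither being characterized by a
constant we could calibrate against).

## Numerical and formatting choices

- **Integer milliseconds** internally; seconds in configs and analysis.
  Event ordering is a stable sort on timestamp, so coincident events
  keep their semantic emission order (e.g. `pump_on` at the triggering
  lick's timestamp follows that `lick_on`).
- **d′ clipping**: rates of exactly 0 or 1 become `1/(2n)` and
  `1 − 1/(2n)` with `n` the per-block count of possible hit or
  false-choice trials on that side (per-block, not per-session).
- **Licking efficiency** attributes reward to the single lick whose
  timestamp triggered the pump; all other licks are unrewarded. Zero
  licks is an error (undefined ratio), not zero.
- **Lick-rate curves**: 100 ms bins aligned to trial start, mean count
  across trials converted to Hz, smoothed by a span-5 centered moving
  average whose window shrinks symmetrically at the edges
  (1, 3, 5, …, 5, 3, 1), leaving constant series unchanged.
- **Trials to criterion** returns the 1-based index of the last trial
  of the first qualifying window (minimum possible value = window
  size); "qualifying" is strictly greater than the criterion rate, so
  20/24 passes and 19/24 does not. NRC (not reaching criterion) is
  represented as `None`.
- Serialized sessions are line-delimited JSON events (sorted keys,
  fixed separators) plus a CSV trial table, all times integer ms, so
  round trips are lossless and identical runs are byte-identical.

## Problem sizes

The test suite and acceptance script run at desk scale: 24–96-trial
sessions for structural properties (4 agents × 4 paradigms × 10 seeds),
600-trial DNMS sessions × 20 seeds for the learning-curve property, and
240 + 600 trials for the reversal property. The whole suite completes
in a few seconds; all numbers reported anywhere in the documentation
are produced by these runs.

## Known limitations

- No hardware models beyond odor kinetics: pump latency is zero, lick
  detection is perfect, port motion is instantaneous events.
- Agents do not model real mice; no parameter here is claimed to fit
  published learning curves.
- The shaping miss-window is implemented as sliding and non-resetting;
  a rig whose firmware resets the window on mode switches would
  alternate modes at a different cadence.
- Inter-day structure (water supplementation, multi-day phase
  progression) is not simulated; each run is a single session.
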