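# odortrain

A software-only, discrete-event re-creation of an automatic training rig
for head-fixed mice performing odor-guided cognitive tasks, together
with the behavioral-analysis toolkit used to score them. Simulated
mouse agents stand in for the animal and the hardware, so the complete
training pipeline — lick teaching, shaping, full task, contingency
reversal — can be executed, tested, and analyzed at a desk.

It is intended for behavioral neuroscientists and rig engineers who
want to prototype protocol logic, validate analysis code against logs
with known ground truth, or generate realistic synthetic session data.

## What it simulates

**Paradigms.** Four olfactory tasks built from 1 s odor pulses and a
lick response window:

- **DNMS** (delayed non-match to sample): sample odor, 4–5 s delay,
  test odor; lick when they differ. ITI 10 s.
- **DPA** (delayed paired association): sample (1-Butanol or Methyl
  butyrate), 8–9 s delay, test (Hexanoic acid or Octane); lick on the
  designated pairs. ITI 16 s.
- **GNG** (Go/No-go): single cue; lick after the Go cue (Hexanoic
  acid), withhold after the No-go cue (Octane). ITI 5 s.
- **GNG reversal**: the GNG map with the cue–reward relationship
  swapped.

A lick inside the half-open response window (0.5–1.5 s after second-odor
offset; 0.5–1.0 s for the DPA task) makes a go trial a **Hit**
(instantaneous ~5 μL reward at the triggering lick) and a nogo trial a
**FalseChoice**; withholding gives **Miss** or **CorrectRejection**.
There is no punishment. Trials come in balanced, seeded blocks of 24.

**Training phases.** `run_lick_teaching_session` (bouts of 10 μL +
4 μL per three licks until 2 s of silence or >200 μL per bout, 400 μL
per session), `run_shaping_session` (rewarded trial types only, with
automatic switching between lick-triggered *self-learning* trials and
port-forward *program-teaching* trials; the day ends at 100 hits), and
`run_task_session` (the full task).

**Agents.** `silent_agent`, `continuous_licker(rate_hz)`,
`bernoulli_agent(p_by_type)`, and `delta_rule_learner(alpha, p0)` — a
Rescorla–Wagner learner over odor sequences, `V ← V + α(r − V)` on
licked trials only, which licks with probability `V`.

**Olfactometer kinetics.** Delivered odor concentration is modeled as a
single exponential per phase, calibrated per odorant from the measured
rising latency `L95` (time to 95% of plateau, so `τ_r = L95 / ln 20`)
and decay constant `τ_d`.

**Analysis.** Blocked performance `(hits + correct rejections)/total`,
hit/false-choice/correct-rejection rates, discriminability
`d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-choice rate)` with extreme rates
clipped to `1/(2n)` and `1 − 1/(2n)`, licking efficiency, 100 ms
lick-rate curves with span-5 smoothing, trials-to-criterion (first
24-trial sliding window strictly above 80%) and the well-trained test
(three consecutive qualifying windows).

## Worked example

```python
import odortrain as ot

cfg = ot.default_config("DNMS")
agent = ot.delta_rule_learner(alpha=0.1, p0=0.6, seed=0)
record = ot.run_task_session(cfg, agent, seed=0, n_trials=600)

blocks = ot.block_stats_frame(record.results)
print(blocks[["block_index", "performance", "hit_rate", "cr_rate", "d_prime"]]
      .iloc[[0, 12, 24]].to_string(index=False))
crit = ot.trials_to_criterion(record.results)
print("trials to criterion:", crit.trials_to_criterion,
      "| well trained:", crit.well_trained)
```

prints

```
 block_index  performance  hit_rate  cr_rate  d_prime
           1     0.666667  0.666667 0.666667 0.861455
          13     0.958333  1.000000 0.916667 3.114659
          25     1.000000  1.000000 1.000000 3.463329
trials to criterion: 86 | well trained: True
```

Read: in block 1 the agent barely discriminates (it licks on two thirds
of both trial types, d′ ≈ 0.86). By block 13 it hits every go trial
while rejecting 92% of nogo trials, and in the last block
discrimination sits at the clipped ceiling — with 12 go and 12 nogo
trials a perfect block gives d′ = 2·Φ⁻¹(23/24) ≈ 3.46. The first
24-trial window above the 80% criterion is completed at trial 86.

The same workflow is available from a shell:

```sh
odortrain simulate --paradigm dnms --agent delta --agent-param alpha=0.1 \
    --n-trials 600 --seed 0 --out session0
odortrain analyze --in session0 --out summary.csv
```

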