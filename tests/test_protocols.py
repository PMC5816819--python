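"""Protocol state machines: scheduling, classification, session engines."""

import dataclasses
from collections import Counter

import pytest

from odortrain import agents
from odortrain.core import TrialSpec, default_config, validate_event_log
from odortrain.protocols import (
    apply_reversal,
    classify_response,
    contingency_for,
    response_window_rel_trial_s,
    run_lick_teaching_session,
    run_shaping_session,
    run_task_session,
    schedule_trials,
)


class TestContingency:
    def test_dnms_rewards_nonmatch(self):
        cmap = contingency_for("DNMS")
        for (s, t), tt in cmap.mapping.items():
            assert tt == ("go" if s != t else "nogo")

    def test_dpa_rewards_designated_pairs(self):
        cmap = contingency_for("DPA")
        gos = set(cmap.go_sequences())
        assert gos == {("1-Butanol", "Hexanoic acid"), ("Methyl butyrate", "Octane")}

    def test_gng_reversal_swaps_cues(self):
        cmap = contingency_for("GNG")
        assert cmap.trial_type("Hexanoic acid", None) == "go"
        rev = apply_reversal(cmap)
        assert rev.trial_type("Hexanoic acid", None) == "nogo"
        assert rev.trial_type("Octane", None) == "go"

    def test_reversal_is_involution(self):
        cmap = contingency_for("GNG")
        assert apply_reversal(apply_reversal(cmap)) == cmap

    def test_reversal_rejects_two_odor_paradigms(self):
        with pytest.raises(ValueError, match="only for GNG"):
            apply_reversal(contingency_for("DNMS"))


class TestScheduling:
    @pytest.mark.parametrize("paradigm,n_types", [("DNMS", 4), ("DPA", 4), ("GNG", 2)])
    def test_blocks_are_balanced(self, paradigm, n_types):
        specs = schedule_trials(paradigm, 72, seed=1)
        for b in range(0, 72, 24):
            block = specs[b : b + 24]
            seqs = Counter((s.sample_odor, s.test_odor) for s in block)
            assert len(seqs) == n_types
            assert all(c == 24 // n_types for c in seqs.values())
            types = Counter(s.trial_type for s in block)
            assert types["go"] == types["nogo"] == 12

    def test_seeded_schedule_is_reproducible(self):
        a = schedule_trials("DNMS", 24, seed=1)
        b = schedule_trials("DNMS", 24, seed=1)
        assert a == b
        assert a != schedule_trials("DNMS", 24, seed=2)

    def test_delays_drawn_within_range(self):
        for s in schedule_trials("DPA", 24, seed=3):
            assert 8.0 <= s.delay_s <= 9.0

    def test_non_multiple_of_block_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            schedule_trials("DNMS", 25, seed=0)


class TestClassifyResponse:
    @pytest.fixture
    def go_spec(self):
        return TrialSpec(
            index=1, paradigm="GNG", sample_odor="Hexanoic acid", test_odor=None,
            trial_type="go", odor_duration_s=1.0, delay_s=None,
            response_window_s=(0.5, 1.5), iti_s=5.0,
        )

    def test_lick_inside_window_is_hit(self, go_spec):
        # window spans 1.5-2.5 s from trial start (cue offset + 0.5-1.5)
        assert classify_response(go_spec, [1.9]) == "Hit"

    def test_half_open_boundaries(self, go_spec):
        w0, w1 = response_window_rel_trial_s(go_spec)
        assert classify_response(go_spec, [w0]) == "Hit"
        assert classify_response(go_spec, [w1]) == "Miss"

    def test_out_of_window_licks_never_change_outcome(self, go_spec):
        w0, w1 = response_window_rel_trial_s(go_spec)
        assert classify_response(go_spec, [0.1, w1 + 1.0]) == "Miss"
        nogo = dataclasses.replace(go_spec, trial_type="nogo", sample_odor="Octane")
        assert classify_response(nogo, [0.1]) == "CorrectRejection"
        assert classify_response(nogo, [w0 + 0.1]) == "FalseChoice"

    def test_unsorted_licks_rejected(self, go_spec):
        with pytest.raises(ValueError, match="sorted"):
            classify_response(go_spec, [2.0, 1.9])


class TestTaskSession:
    def test_silent_agent_counts_and_reward(self, dnms_config):
        rec = run_task_session(dnms_config, agents.silent_agent(), seed=1, n_trials=24)
        assert rec.outcome_counts == {
            "Hit": 0, "Miss": 12, "FalseChoice": 0, "CorrectRejection": 12,
        }
        assert rec.total_reward_uL == 0.0

    def test_always_lick_agent_counts_and_reward(self, dnms_config):
        rec = run_task_session(
            dnms_config, agents.continuous_licker(8.0), seed=1, n_trials=24
        )
        assert rec.outcome_counts == {
            "Hit": 12, "Miss": 0, "FalseChoice": 12, "CorrectRejection": 0,
        }
        assert rec.total_reward_uL == 12 * 5.0

    def test_zero_trials_yields_only_session_end(self, dnms_config):
        rec = run_task_session(dnms_config, agents.silent_agent(), seed=1, n_trials=0)
        assert rec.results == []
        assert [e.kind for e in rec.events] == ["session_end"]

    def test_event_timing_invariants(self, dnms_config):
        rec = run_task_session(
            dnms_config, agents.continuous_licker(8.0), seed=5, n_trials=24
        )
        odor_on = [e for e in rec.events if e.kind == "odor_on"]
        odor_off = [e for e in rec.events if e.kind == "odor_off"]
        for on, off in zip(odor_on, odor_off):
            assert off.t_ms - on.t_ms == 1000
        starts = [e.t_ms for e in rec.events if e.kind == "trial_start"]
        ends = [e.t_ms for e in rec.events if e.kind == "trial_end"]
        for nxt, end in zip(starts[1:], ends):
            assert nxt - end == 10_000
        # delay between sample offset and test onset stays in range
        for i in range(0, len(odor_on), 2):
            delay = odor_on[i + 1].t_ms - odor_off[i].t_ms
            assert 4000 <= delay <= 5000

    def test_reward_pump_fires_at_first_in_window_lick(self, dnms_config):
        rec = run_task_session(
            dnms_config, agents.continuous_licker(8.0), seed=2, n_trials=24
        )
        pumps = [e for e in rec.events if e.kind == "pump_on"]
        assert len(pumps) == 12
        licks = {e.t_ms for e in rec.events if e.kind == "lick_on"}
        for p in pumps:
            assert p.payload["trigger"] == "lick"
            assert p.payload["lick_t_ms"] in licks

    def test_engine_logs_are_always_valid(self, dnms_config):
        for agent in (agents.silent_agent(), agents.continuous_licker(8.0),
                      agents.delta_rule_learner(seed=3)):
            rec = run_task_session(dnms_config, agent, seed=3, n_trials=24)
            assert validate_event_log(rec.events) == []

    def test_agent_exception_flags_partial_record(self, dnms_config):
        class Broken(agents.Agent):
            def decide(self, ctx):
                if ctx.index == 3:
                    raise RuntimeError("sensor detached")
                return []

        rec = run_task_session(dnms_config, Broken(), seed=1, n_trials=24)
        assert rec.partial
        assert "sensor detached" in rec.termination_reason
        assert len(rec.results) == 2


class TestShapingSession:
    def test_always_licker_ends_at_exact_hit_target(self):
        cfg = default_config("DNMS", phase="shape")
        rec = run_shaping_session(cfg, agents.continuous_licker(8.0), seed=1)
        assert rec.totals["hits"] == 100
        assert rec.termination_reason == "hit_target"
        assert all(r.mode == "self_learning" for r in rec.results)

    def test_only_go_trials_are_scheduled(self):
        cfg = default_config("DPA", phase="shape")
        rec = run_shaping_session(cfg, agents.continuous_licker(8.0), seed=2)
        assert all(r.spec.trial_type == "go" for r in rec.results)

    def test_silent_agent_locks_into_program_teaching(self):
        cfg = default_config("DNMS", phase="shape", max_trials=60,
                             max_duration_s=36_000)
        rec = run_shaping_session(cfg, agents.silent_agent(), seed=1)
        # oracle: step through the switching rules -- five straight misses
        # trip the sliding-window trigger, and with no licks the teaching
        # mode never releases
        assert [r.mode for r in rec.results[:5]] == ["self_learning"] * 5
        assert all(r.mode == "program_teaching" for r in rec.results[5:])
        assert rec.totals["hits"] == 0
        assert rec.termination_reason in ("max_trials", "max_duration")
        # automatic deliveries are logged as reward but never as Hits
        assert rec.total_reward_uL == 55 * 5.0

    def test_teaching_only_licker_alternates_modes(self):
        class TeachingOnly(agents.Agent):
            def decide(self, ctx):
                if ctx.mode == "program_teaching":
                    return [ctx.window_mid_ms]
                return []

        cfg = default_config("DNMS", phase="shape", max_trials=40,
                             max_duration_s=36_000)
        rec = run_shaping_session(cfg, TeachingOnly(), seed=1)
        modes = [r.mode for r in rec.results]
        # state-machine trace: 5 self-learning misses, then teaching; each
        # licked teaching trial releases to self-learning, whose miss
        # immediately re-trips the (still saturated) sliding window
        assert modes[:6] == ["self_learning"] * 5 + ["program_teaching"]
        for i in range(6, len(modes)):
            assert modes[i] != modes[i - 1]

    def test_shaping_determinism(self):
        cfg = default_config("GNG", phase="shape")
        a = run_shaping_session(cfg, agents.delta_rule_learner(seed=4), seed=4)
        b = run_shaping_session(cfg, agents.delta_rule_learner(seed=4), seed=4)
        assert a.events == b.events and a.results == b.results


class TestLickTeachingSession:
    def test_continuous_licker_bout_and_session_volumes(self):
        cfg = default_config("DNMS", phase="teach")
        rec = run_lick_teaching_session(cfg, agents.continuous_licker(8.0), seed=1)
        # drop schedule arithmetic: 10 + 4 * 48 = 202 > 200 ends each bout;
        # two bouts reach the 400 uL session target
        assert rec.totals["bout_volumes_uL"] == [202.0, 202.0]
        assert rec.total_reward_uL == 404.0
        assert rec.termination_reason == "volume_target"

    def test_silent_agent_bouts_deliver_only_initial_drop(self):
        cfg = default_config("DNMS", phase="teach", teaching_max_bouts=5)
        rec = run_lick_teaching_session(cfg, agents.silent_agent(), seed=1)
        assert rec.totals["bout_volumes_uL"] == [10.0] * 5
        assert rec.termination_reason == "max_bouts"
        # each bout times out 2 s after its start, with no licks logged
        assert not any(e.kind == "lick_on" for e in rec.events)
        forwards = [e.t_ms for e in rec.events if e.kind == "port_forward"]
        backs = [e.t_ms for e in rec.events if e.kind == "port_back"]
        assert all(b - f == 2000 for f, b in zip(forwards, backs))

    def test_no_bout_starts_after_target_reached(self):
        cfg = default_config("DNMS", phase="teach", session_volume_target_uL=150.0)
        rec = run_lick_teaching_session(cfg, agents.continuous_licker(8.0), seed=1)
        assert rec.totals["bouts"] == 1
        assert rec.termination_reason == "volume_target"

    def test_teaching_emits_no_odor_events(self):
        cfg = default_config("DNMS", phase="teach")
        rec = run_lick_teaching_session(cfg, agents.continuous_licker(8.0), seed=1)
        assert not any(e.kind.startswith("odor") for e in rec.events)
        assert validate_event_log(rec.events) == []

    def test_pump_volume_conservation(self):
        cfg = default_config("DNMS", phase="teach")
        rec = run_lick_teaching_session(cfg, agents.continuous_licker(8.0), seed=1)
        pumped = sum(
            e.payload["volume_uL"] for e in rec.events if e.kind == "pump_on"
        )
        assert pumped == rec.total_reward_uL
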