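"""Blocking schedule and PRL environment contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paralearn.tasks import (
    DEFAULT_TRIAL_TYPES,
    TrialTypeSpec,
    build_blocking_design,
    build_prl_session,
    emit_trials,
    first_probe_index,
    play_prl,
)


class TestBlockingDesign:
    def test_default_schedule_is_154_trials(self, default_design):
        assert default_design.n_trials == 154
        assert len(default_design.trial_types) == 7

    def test_phase_repetition_counts(self, default_trials):
        for tt in DEFAULT_TRIAL_TYPES:
            per_phase = [sum(1 for t in default_trials
                             if t.category_id == tt.category_id and t.phase == ph)
                         for ph in (1, 2, 3)]
            assert per_phase == [10, 6, 6]

    def test_phases_are_contiguous(self, default_trials):
        phases = [t.phase for t in default_trials]
        assert phases == sorted(phases)
        assert sum(t.is_first_of_phase for t in default_trials) == 2

    def test_minimal_design_orders_phases(self):
        tt = (TrialTypeSpec("x", (("A",), ("A", "B"), ("B",)), (1, 1, -1)),)
        trials = emit_trials(build_blocking_design(tt, reps_per_phase=(1, 1, 1)))
        assert [t.phase for t in trials] == [1, 2, 3]

    def test_seed_determinism_and_within_phase_shuffle(self):
        a = build_blocking_design(seed=7)
        b = build_blocking_design(seed=7)
        c = build_blocking_design(seed=8)
        assert a.presentation_order == b.presentation_order
        assert a.presentation_order != c.presentation_order
        # different seeds still keep phases aligned
        assert [ph for _, ph in a.presentation_order] == [
            ph for _, ph in c.presentation_order]

    def test_first_phase3_probe_is_feedback_free(self, default_trials):
        for cid in ("block_confirm", "block_control"):
            i = first_probe_index(default_trials, cid)
            assert default_trials[i].gives_feedback is False
            later = [t for t in default_trials
                     if t.category_id == cid and t.phase == 3 and t.index > i]
            assert all(t.gives_feedback for t in later)

    def test_rejects_invalid_specs(self):
        with pytest.raises(ValueError, match="1 or 2 cues"):
            TrialTypeSpec("bad", (("A", "B", "C"), ("A",), ("A",)), (1, 1, 1))
        dup = (DEFAULT_TRIAL_TYPES[0], DEFAULT_TRIAL_TYPES[0])
        with pytest.raises(ValueError, match="duplicate category_id"):
            build_blocking_design(dup)
        with pytest.raises(ValueError):
            build_blocking_design(())

    @settings(max_examples=25, derandomize=True)
    @given(n_types=st.integers(1, 5),
           reps=st.tuples(*[st.integers(1, 6)] * 3),
           seed=st.integers(0, 1000))
    def test_trial_count_conservation(self, n_types, reps, seed):
        tts = tuple(
            TrialTypeSpec(f"t{i}", ((f"P{i}",), (f"P{i}", f"S{i}"), (f"S{i}",)),
                          (1, 1, -1))
            for i in range(n_types)
        )
        design = build_blocking_design(tts, reps, seed=seed)
        trials = emit_trials(design)
        assert len(trials) == n_types * sum(reps)
        assert [t.index for t in trials] == list(range(len(trials)))


class TestPRL:
    def test_default_session_structure(self):
        s = build_prl_session()
        assert s.n_trials == 160 and s.n_blocks == 2 and s.trials_per_block == 80

    def test_rejects_tied_maxima_and_bad_probs(self):
        with pytest.raises(ValueError, match="tied maximum"):
            build_prl_session(block_probs=((0.9, 0.9, 0.1),))
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            build_prl_session(block_probs=((1.2, 0.5, 0.1),))

    def test_best_deck_agent_triggers_reversal_at_criterion(self):
        s = build_prl_session(seed=3)
        played = play_prl(s, lambda t, c, o: 0)  # deck 0 is best in block 1
        # 9-of-10 first satisfiable after trial 9; reversal takes effect at 10
        assert played.reversal_trials[0] == 10

    def test_reversal_rule_soundness_random_agent(self):
        rng = np.random.default_rng(5)
        s = build_prl_session(seed=5)
        played = play_prl(s, lambda t, c, o: int(rng.integers(0, 3)), seed=5)
        probs = played.deck_probs
        best = np.argmax(probs, axis=1)
        hit = played.choices == best
        boundaries = set(played.reversal_trials)
        for t in range(10, played.n_trials):
            window_ok = hit[t - 10:t].sum() >= 9
            # windows may not span a reversal or block boundary (counters reset)
            clean = not any(b > t - 10 and b <= t for b in boundaries | {80})
            if window_ok and clean and t != 80:
                assert t in boundaries, f"missed reversal at {t}"
        for t in played.reversal_trials:
            assert hit[t - 10:t].sum() >= 9, f"spurious reversal at {t}"

    def test_seeded_sessions_reproduce(self):
        def agent(t, c, o):
            return t % 3

        a = play_prl(build_prl_session(seed=9), agent)
        b = play_prl(build_prl_session(seed=9), agent)
        assert np.array_equal(a.outcomes, b.outcomes)
        assert a.reversal_trials == b.reversal_trials

    def test_degenerate_probabilities(self):
        # criterion window longer than the session: no reversal interferes
        s = build_prl_session(block_probs=((1.0, 0.5, 0.0),), n_trials=40,
                              n_blocks=1, criterion=(9, 60))
        sure = play_prl(s, lambda t, c, o: 0)
        assert np.all(sure.outcomes == 100)
        s = build_prl_session(block_probs=((1.0, 0.5, 0.0),), n_trials=40,
                              n_blocks=1, criterion=(9, 60))
        never = play_prl(s, lambda t, c, o: 2)
        assert np.all(never.outcomes == -50)

    def test_win_rate_matches_deck_probability(self):
        # deck 1 (p=0.8) is never the best deck, so no reversals interfere
        s = build_prl_session(block_probs=((0.9, 0.8, 0.1),), n_trials=10_000,
                              n_blocks=1, seed=11)
        played = play_prl(s, lambda t, c, o: 1)
        assert abs((played.outcomes == 100).mean() - 0.8) < 0.01

    def test_agent_out_of_range_rejected(self):
        s = build_prl_session()
        with pytest.raises(ValueError, match="outside"):
            play_prl(s, lambda t, c, o: 5)
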