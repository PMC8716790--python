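"""State-machine semantics: counters, blanking, duty cycle, lock detection.

The core check is equivalence with an independently written step-by-step
reference simulator over random LD sequences and configurations.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cldbs.detector import (
    Detector,
    DetectorConfig,
    StateTrace,
    detect_lock,
    duty_cycle,
    run_detector,
)


def naive_detector(ld, thresholds, onset, term, blank_updates, update_interval,
                   initial=0):
    """Plain-python reference: consecutive-update counters, >= threshold
    comparison, adjacent transitions, blanked updates ignored for counting."""
    n_states = len(thresholds) + 1
    state, up, down = initial, 0, 0
    blanked_left = 0
    out = []
    for v in ld:
        if blanked_left > 0:
            blanked_left -= 1
            out.append(state)
            continue
        rise_ok = state < n_states - 1 and v >= thresholds[state]
        fall_ok = state > 0 and v < thresholds[state - 1]
        up = up + 1 if (state < n_states - 1 and rise_ok) else 0
        down = down + 1 if (state > 0 and fall_ok) else 0
        if state < n_states - 1 and up >= onset:
            state += 1
            up = down = 0
            blanked_left = blank_updates
        elif state > 0 and down >= term:
            state -= 1
            up = down = 0
            blanked_left = blank_updates
        out.append(state)
    return np.array(out)


class TestRunDetector:
    def test_rise_exactly_at_counter_th_update(self):
        # update 0.5 s, onset counter 4 -> 2.0 s onset duration
        cfg = DetectorConfig(thresholds=[0.5], onset_counter=4,
                             termination_counter=2, update_interval=0.5)
        assert cfg.onset_duration == pytest.approx(2.0)
        ld = np.r_[np.zeros(3), np.ones(7), np.zeros(5)]
        trace = run_detector(ld, cfg)
        t_change, frm, to, cause = trace.changes[0]
        assert (frm, to) == (0, 1)
        # supra run starts at update index 3; 4th consecutive is index 6
        assert t_change == pytest.approx(6 * 0.5)
        assert trace.state[5] == 0 and trace.state[6] == 1

    def test_always_below_threshold_stays_zero(self):
        cfg = DetectorConfig(thresholds=[1.0], onset_counter=2)
        trace = run_detector(np.zeros(200), cfg)
        assert np.all(trace.state == 0)
        assert trace.changes == []

    def test_equivalence_with_naive_reference_over_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n_thr = int(rng.integers(1, 3))
            thresholds = sorted(rng.normal(0, 1, n_thr).tolist())
            if n_thr == 2 and thresholds[0] == thresholds[1]:
                thresholds[1] += 0.1
            onset = int(rng.integers(1, 5))
            term = int(rng.integers(1, 5))
            blank_updates = int(rng.integers(0, 4))
            upd = 0.5
            cfg = DetectorConfig(
                thresholds=thresholds, onset_counter=onset,
                termination_counter=term, blanking=blank_updates * upd,
                update_interval=upd,
            )
            ld = rng.normal(0, 1.2, int(rng.integers(20, 80)))
            got = run_detector(ld, cfg).state
            want = naive_detector(ld, thresholds, onset, term, blank_updates,
                                  upd)
            assert np.array_equal(got, want)

    def test_determinism(self):
        rng = np.random.default_rng(1)
        ld = rng.normal(0, 1, 300)
        cfg = DetectorConfig(thresholds=[0.3], onset_counter=2,
                             termination_counter=3, blanking=1.0)
        a = run_detector(ld, cfg)
        b = run_detector(ld, cfg)
        assert np.array_equal(a.state, b.state)
        assert a.changes == b.changes

    @given(
        t1=st.floats(-1.0, 1.0),
        delta=st.floats(0.1, 1.0),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_raising_threshold_never_increases_high_time(self, t1, delta, seed):
        ld = np.random.default_rng(seed).normal(0, 1, 200)
        base = dict(onset_counter=2, termination_counter=2)
        lo = run_detector(ld, DetectorConfig(thresholds=[t1], **base))
        hi = run_detector(ld, DetectorConfig(thresholds=[t1 + delta], **base))
        assert np.mean(hi.state >= 1) <= np.mean(lo.state >= 1)

    @given(a=st.integers(1, 6), b=st.integers(1, 6), seed=st.integers(0, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_minimal_supra_run_length_is_exactly_the_onset_counter(self, a, b,
                                                                   seed):
        cfg = DetectorConfig(thresholds=[0.5], onset_counter=a,
                             termination_counter=b)
        pad = np.zeros(3)
        run_a = np.r_[pad, np.ones(a), np.zeros(5)]
        run_a1 = np.r_[pad, np.ones(a - 1), np.zeros(5)] if a > 1 else None
        assert np.any(run_detector(run_a, cfg).state == 1)
        if run_a1 is not None:
            assert np.all(run_detector(run_a1, cfg).state == 0)

    def test_two_threshold_transitions_are_adjacent_only(self):
        rng = np.random.default_rng(3)
        ld = rng.normal(0, 2, 2000)
        cfg = DetectorConfig(thresholds=[-0.5, 0.5], onset_counter=1,
                             termination_counter=1)
        trace = run_detector(ld, cfg)
        for _, frm, to, _ in trace.changes:
            assert abs(frm - to) == 1
        assert np.all(np.abs(np.diff(trace.state)) <= 1)

    def test_blanking_suppresses_state_changes(self):
        upd = 0.5
        cfg = DetectorConfig(thresholds=[0.5], onset_counter=1,
                             termination_counter=1, blanking=3 * upd,
                             update_interval=upd)
        ld = np.r_[np.zeros(2), [1.0], np.zeros(10)]
        trace = run_detector(ld, cfg)
        # rise at index 2, then termination cannot occur before blanking ends
        fall_idx = np.flatnonzero(np.diff(trace.state) == -1)
        assert trace.state[2] == 1
        assert fall_idx[0] * upd >= trace.changes[0][0] + cfg.blanking

    def test_empty_ld_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_detector(np.array([]), DetectorConfig(thresholds=[0.0]))


class TestDutyCycle:
    def test_constant_state(self):
        trace = StateTrace(np.arange(10) * 0.5, np.ones(10, int))
        assert duty_cycle(trace) == {1: 1.0}

    def test_alternating_states_split_evenly(self):
        cfg = DetectorConfig(thresholds=[0.5], onset_counter=1,
                             termination_counter=1)
        ld = np.tile([1.0, 0.0], 100)
        frac = duty_cycle(run_detector(ld, cfg))
        assert frac[0] == pytest.approx(0.5, abs=0.01)
        assert frac[1] == pytest.approx(0.5, abs=0.01)

    def test_threshold_at_75th_percentile_gives_quarter_occupancy(self):
        rng = np.random.default_rng(4)
        ld = rng.normal(0, 1, 10000)
        thr = np.percentile(ld, 75)
        cfg = DetectorConfig(thresholds=[float(thr)], onset_counter=1,
                             termination_counter=1)
        frac = duty_cycle(run_detector(ld, cfg))
        assert frac.get(1, 0.0) == pytest.approx(0.25, abs=0.02)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        ld = rng.normal(0, 1, 500)
        cfg = DetectorConfig(thresholds=[-0.2, 0.6], onset_counter=1,
                             termination_counter=1)
        assert sum(duty_cycle(run_detector(ld, cfg)).values()) == pytest.approx(1.0)


class TestDetectLock:
    def test_rise_without_fall_is_one_ongoing_episode(self):
        cfg = DetectorConfig(thresholds=[0.5], onset_counter=1,
                             termination_counter=1, update_interval=0.5)
        ld = np.r_[np.zeros(5), np.ones(100)]
        trace = run_detector(ld, cfg)
        episodes = detect_lock(trace, max_dwell=10.0)
        assert len(episodes) == 1
        assert episodes[0].ongoing
        assert episodes[0].end == pytest.approx(trace.times[-1] + 0.5)

    def test_all_zero_state_has_no_episodes(self):
        trace = StateTrace(np.arange(50) * 0.5, np.zeros(50, int))
        assert detect_lock(trace, max_dwell=5.0) == []

    def test_short_dwells_not_reported(self):
        cfg = DetectorConfig(thresholds=[0.5], onset_counter=1,
                             termination_counter=1, update_interval=0.5)
        ld = np.tile(np.r_[np.ones(4), np.zeros(4)], 20)
        trace = run_detector(ld, cfg)
        assert detect_lock(trace, max_dwell=10.0) == []

    def test_invalid_max_dwell(self):
        trace = StateTrace(np.arange(5) * 0.5, np.zeros(5, int))
        with pytest.raises(ValueError):
            detect_lock(trace, max_dwell=0.0)
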