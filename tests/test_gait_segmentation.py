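import numpy as np
import pytest

from gaitseg.gait_segmentation import (
    FOOT_OFF,
    FOOT_STRIKE,
    MID_SWING,
    SEEKING_SWING,
    DetectorConfig,
    DetectorState,
    cycles_from_events,
    detect_events,
    initial_state,
    step_detector,
)
from gaitseg.signal_model import IMURecording
from gaitseg.synthetic_gait import generate_cycle

from conftest import NOISE_FREE_PROFILES


def _chain(keypoints, fs=100.0):
    """Sampled half-cosine chain through (t, v) keypoints (test helper)."""
    kp_t = np.array([t for t, _ in keypoints])
    kp_v = np.array([v for _, v in keypoints])
    ts = np.arange(int(kp_t[-1] * fs) + 1) / fs
    idx = np.clip(np.searchsorted(kp_t, ts, side="right") - 1, 0, len(kp_t) - 2)
    u = (ts - kp_t[idx]) / (kp_t[idx + 1] - kp_t[idx])
    return kp_v[idx] + (kp_v[idx + 1] - kp_v[idx]) * (1 - np.cos(np.pi * u)) / 2


class TestSwingDetection:
    def test_all_zero_signal_no_events(self):
        assert detect_events(np.zeros(500)) == []

    def test_empty_sequence(self):
        assert detect_events([]) == []

    def test_subthreshold_lobe_no_mid_swing(self):
        # swing threshold is strictly greater than 1.8 rad/s
        gz = _chain([(0, -0.5), (0.3, 1.5), (0.6, -0.5), (1.0, 0.0)])
        assert all(e.event_type != MID_SWING for e in detect_events(gz))

    def test_suprathreshold_lobe_emits_mid_swing_at_argmax(self):
        gz = _chain([(0, -0.5), (0.3, 2.5), (0.6, -0.5), (1.0, 0.0)])
        events = detect_events(gz)
        ms = [e for e in events if e.event_type == MID_SWING]
        assert len(ms) == 1
        assert ms[0].sample_index == int(np.argmax(gz))

    def test_exactly_at_threshold_not_emitted(self):
        cfg = DetectorConfig()
        gz = _chain([(0, -0.5), (0.3, cfg.swing_peak_threshold), (0.6, -0.5),
                     (1.0, 0.0)])
        assert all(e.event_type != MID_SWING for e in detect_events(gz, cfg))


class TestFootOffRules:
    def test_noise_free_cycle_events_match_annotation(self):
        # oracle: the template's analytic extrema, via offline argmax/argmin
        rng = np.random.default_rng(0)
        channels, ann = generate_cycle(NOISE_FREE_PROFILES["WK"], rng)
        gz = channels["gz"]
        events = {e.event_type: e for e in detect_events(gz)}
        fs = 100.0
        for etype, t_true in [
            (MID_SWING, ann.mid_swing_s),
            (FOOT_STRIKE, ann.foot_strike_s),
            (FOOT_OFF, ann.end_foot_off_s),
        ]:
            assert etype in events
            assert abs(events[etype].sample_index - t_true * fs) <= 3

    def test_tmin_tmax_gap_50ms_rejected(self):
        # drop from the stance maximum to the minimum takes only 50 ms
        gz = _chain([(0, -2.0), (0.3, 4.0), (0.55, -2.0), (0.80, 0.5),
                     (0.85, -2.0), (1.2, 0.0), (2.0, 0.0)])
        events = detect_events(gz)
        assert all(e.event_type != FOOT_OFF for e in events)

    def test_footoff_value_above_threshold_rejected(self):
        # t_min value 2.0 rad/s > 1.4 rad/s: conjunction fails
        gz = _chain([(0, -2.0), (0.3, 4.2), (0.5, -0.3), (0.80, 3.0),
                     (0.95, 2.0), (1.2, 2.5), (2.0, 2.5)])
        assert all(e.event_type != FOOT_OFF for e in detect_events(gz))

    def test_timeout_discards_pending_swing(self):
        cfg = DetectorConfig()
        gz = _chain([(0, -1.0), (0.25, 3.0), (0.5, -0.5)])
        gz = np.concatenate([gz, np.full(200, -0.01)])  # 2 s of near-silence
        state = initial_state()
        events = []
        for i, v in enumerate(gz):
            state, emitted = step_detector(state, (i, float(v)), cfg)
            events.extend(emitted)
        assert state.phase == SEEKING_SWING
        assert all(e.event_type != FOOT_OFF for e in events)

    def test_eq2_reconstructable_post_hoc(self, walking_session):
        # every FOOT_OFF satisfies the printed conjunction at its index
        rec, _ = walking_session
        cfg = DetectorConfig()
        events = detect_events(rec.gz, cfg)
        by_type = {}
        last_fs = None
        for e in events:
            if e.event_type == FOOT_STRIKE:
                last_fs = e
            elif e.event_type == FOOT_OFF:
                assert e.value <= cfg.footoff_value_threshold
                assert e.value == rec.gz[e.sample_index]
                # t_min - t_max >= 60 ms and t_max - t_fs >= 70 ms imply
                # t_min - t_fs >= 130 ms
                assert last_fs is not None
                assert (e.sample_index - last_fs.sample_index) / cfg.fs >= 0.130


class TestEventStream:
    def test_cyclic_event_order(self, walking_session):
        rec, _ = walking_session
        events = detect_events(rec.gz)
        order = {MID_SWING: 0, FOOT_STRIKE: 1, FOOT_OFF: 2}
        codes = [order[e.event_type] for e in events]
        for a, b in zip(codes, codes[1:]):
            # next type either continues the triple or restarts at MID_SWING
            assert b == (a + 1) % 3 or b == 0
        times = [e.time_s for e in events]
        assert times == sorted(times)
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_twenty_cycle_session_all_foot_offs_recovered(self, walking_session):
        rec, ann = walking_session
        events = detect_events(rec.gz)
        fo = np.array([e.time_s for e in events if e.event_type == FOOT_OFF])
        assert len(ann.cycles) == 20
        for t_true in ann.foot_off_times():
            assert np.min(np.abs(fo - t_true)) <= 0.030

    def test_streaming_equals_batch_in_chunks_of_7(self, walking_session):
        rec, _ = walking_session
        gz = rec.gz[:3000]
        whole = detect_events(gz)
        state = initial_state()
        chunked = []
        for start in range(0, len(gz), 7):
            for i in range(start, min(start + 7, len(gz))):
                state, emitted = step_detector(state, (i, float(gz[i])),
                                               DetectorConfig())
                chunked.extend(emitted)
        assert chunked == whole

    def test_determinism(self, walking_session):
        rec, _ = walking_session
        assert detect_events(rec.gz) == detect_events(rec.gz)

    def test_constant_bias_shifts_foot_offs_at_most_one_sample(
        self, clean_walking_session
    ):
        rec, _ = clean_walking_session
        base = [e.sample_index for e in detect_events(rec.gz)
                if e.event_type == FOOT_OFF]
        for c in (-0.04, 0.04):
            shifted = [e.sample_index for e in detect_events(rec.gz + c)
                       if e.event_type == FOOT_OFF]
            assert len(shifted) == len(base)
            assert max(abs(a - b) for a, b in zip(base, shifted)) <= 1

    def test_out_of_order_sample_rejected(self):
        state = initial_state()
        state, _ = step_detector(state, (0, 0.0), DetectorConfig())
        with pytest.raises(ValueError, match="out-of-order"):
            step_detector(state, (2, 0.0), DetectorConfig())

    def test_non_finite_sample_reports_index(self):
        state = initial_state()
        state, _ = step_detector(state, (0, 0.0), DetectorConfig())
        with pytest.raises(ValueError, match="index 1"):
            step_detector(state, (1, float("nan")), DetectorConfig())

    def test_state_memory_is_constant(self):
        # no windows or growing buffers: every field is a scalar
        for f in DetectorState.__dataclass_fields__.values():
            assert f.type in ("str", "int", "float", "bool")


class TestCyclesFromEvents:
    def _recording(self, n=1000, labels=None):
        kwargs = {c: np.zeros(n) for c in ("ax", "ay", "az", "gx", "gy", "gz")}
        return IMURecording(
            time=np.arange(n) / 100.0,
            labels=labels if labels is not None else np.empty(0, dtype=object),
            **kwargs,
        )

    def _fo(self, i):
        from gaitseg.gait_segmentation import GaitEvent
        return GaitEvent(FOOT_OFF, i, i / 100.0, -2.0)

    def test_fewer_than_two_foot_offs_no_cycles(self):
        rec = self._recording()
        assert cycles_from_events([], rec) == []
        assert cycles_from_events([self._fo(10)], rec) == []

    def test_five_foot_offs_make_four_shared_boundary_cycles(self):
        rec = self._recording()
        events = [self._fo(i) for i in (100, 200, 300, 400, 500)]
        cycles = cycles_from_events(events, rec)
        assert len(cycles) == 4
        for a, b in zip(cycles, cycles[1:]):
            assert a.end is b.start
            assert a.segment.end_index == b.segment.start_index

    def test_majority_label(self):
        labels = np.array(["WK"] * 60 + ["STAND"] * 40, dtype=object)
        rec = self._recording(n=100, labels=labels)
        cycles = cycles_from_events([self._fo(0), self._fo(100)], rec)
        assert cycles[0].activity_label == "WK"

    def test_label_tie_broken_toward_earlier_run(self):
        labels = np.array(["SD"] * 50 + ["WK"] * 50, dtype=object)
        rec = self._recording(n=100, labels=labels)
        cycles = cycles_from_events([self._fo(0), self._fo(100)], rec)
        assert cycles[0].activity_label == "SD"

    def test_other_event_types_ignored_for_boundaries(self):
        from gaitseg.gait_segmentation import GaitEvent
        rec = self._recording()
        events = [
            self._fo(100),
            GaitEvent(MID_SWING, 150, 1.5, 4.0),
            GaitEvent(FOOT_STRIKE, 180, 1.8, -2.0),
            self._fo(220),
        ]
        cycles = cycles_from_events(events, rec)
        assert len(cycles) == 1
        assert (cycles[0].segment.start_index, cycles[0].segment.end_index) == (100, 220)
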