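import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from motionlab import gait as G
from motionlab import synthgen
from motionlab.errors import (DetectionError, OrderingError, ValidationError)
from motionlab.gait import GaitEvent


def _ev(typ, t, side="left"):
    return GaitEvent(typ, side, int(round(t * 100)), float(t))


class TestValidateEvents:
    def test_minimal_cycle(self):
        cycles = G.validate_events([_ev("heel_strike", 0), _ev("toe_off", 4),
                                    _ev("heel_strike", 6)], "left")
        assert len(cycles) == 1

    def test_toe_off_first_rejected(self):
        with pytest.raises(OrderingError, match="heel_strike"):
            G.validate_events([_ev("toe_off", 0), _ev("heel_strike", 2),
                               _ev("toe_off", 4), _ev("heel_strike", 6)], "left")

    def test_optional_events_attach_to_cycle(self):
        cycles = G.validate_events([
            _ev("heel_strike", 0), _ev("heel_off", 2), _ev("toe_off", 4),
            _ev("max_toe_lift", 5), _ev("heel_strike", 6)], "left")
        assert cycles[0]["heel_off"].time == 2.0
        assert cycles[0]["max_toe_lift"].time == 5.0

    def test_double_toe_off_rejected(self):
        with pytest.raises(OrderingError, match="toe_off"):
            G.validate_events([_ev("heel_strike", 0), _ev("toe_off", 2),
                               _ev("toe_off", 4), _ev("heel_strike", 6)], "left")


class TestComputeCycles:
    def test_dummy_gait_paper_values(self, gait_bundle):
        cycles = G.compute_cycles(gait_bundle.elements["left_leg"],
                                  gait_bundle.events, "left")
        assert len(cycles) == 2
        for c in cycles:
            assert c.stride_length == pytest.approx(7.0)
            assert c.toe_lift_height == pytest.approx(0.5)
            assert c.stance_duration == pytest.approx(4.0)
            assert c.swing_duration == pytest.approx(2.0)

    def test_stance_plus_swing_equals_stride(self, gait_bundle):
        for c in G.compute_cycles(gait_bundle.elements["left_leg"],
                                  gait_bundle.events, "left"):
            assert c.stance_duration + c.swing_duration == pytest.approx(
                c.stride_duration, abs=1e-9)

    def test_stride_lengths_sum_to_total_progression(self, gait_bundle):
        e = gait_bundle.elements["left_leg"]
        cycles = G.compute_cycles(e, gait_bundle.events, "left")
        heel = e.poi("heel")
        hs = sorted([ev for ev in gait_bundle.events
                     if ev.side == "left" and ev.type == "heel_strike"],
                    key=lambda ev: ev.time)
        total = abs(heel.coords[hs[-1].frame, 0] - heel.coords[hs[0].frame, 0])
        assert sum(c.stride_length for c in cycles) == pytest.approx(total)

    def test_toe_lift_speed_is_height_over_duration(self, gait_bundle):
        c = G.compute_cycles(gait_bundle.elements["left_leg"],
                             gait_bundle.events, "left")[0]
        assert c.toe_lift_speed == pytest.approx(
            c.toe_lift_height / c.toe_lift_duration)

    @given(st.lists(st.floats(min_value=0.5, max_value=4.0),
                    min_size=2, max_size=5),
           st.floats(min_value=0.05, max_value=0.45))
    def test_stance_swing_stride_identity_on_random_streams(self, strides,
                                                            stance_frac):
        # random valid event streams: HS at cumulative stride times,
        # TO a fixed fraction into each cycle
        hs_times = np.concatenate([[0.0], np.cumsum(strides)])
        events = []
        for k, t0 in enumerate(hs_times):
            events.append(GaitEvent("heel_strike", "left", k * 10, float(t0)))
            if k + 1 < len(hs_times):
                to = t0 + stance_frac * (hs_times[k + 1] - t0)
                events.append(GaitEvent("toe_off", "left", k * 10 + 5, float(to)))
        for cyc in G.validate_events(events, "left"):
            stance = cyc["toe_off"].time - cyc["heel_strike"].time
            swing = cyc["next_heel_strike"].time - cyc["toe_off"].time
            stride = cyc["next_heel_strike"].time - cyc["heel_strike"].time
            assert stance + swing == pytest.approx(stride, abs=1e-9)


class TestStepParameters:
    def test_symmetric_gait_half_stride_steps(self, gait_bundle):
        e = gait_bundle.elements["legs"]
        steps = G.step_parameters(
            e, gait_bundle.events,
            heel_poi={"left": "heel_left", "right": "heel_right"})
        assert steps, "expected at least one step"
        for s in steps:
            assert s["step_duration"] == pytest.approx(3.0)
            assert s["step_size"] == pytest.approx(3.5)

    def test_step_durations_sum_to_stride(self, gait_bundle):
        e = gait_bundle.elements["legs"]
        steps = G.step_parameters(
            e, gait_bundle.events,
            heel_poi={"left": "heel_left", "right": "heel_right"})
        lr = next(s for s in steps if s["from_side"] == "left")
        rl = next(s for s in steps if s["from_side"] == "right")
        assert lr["step_duration"] + rl["step_duration"] == pytest.approx(6.0)

    def test_single_side_rejected(self, gait_bundle):
        left_only = [ev for ev in gait_bundle.events if ev.side == "left"]
        with pytest.raises(ValidationError):
            G.step_parameters(gait_bundle.elements["legs"], left_only,
                              heel_poi={"left": "heel_left",
                                        "right": "heel_right"})


class TestGaitDiagram:
    def test_interval_intersection(self):
        events = ([_ev("heel_strike", 0), _ev("toe_off", 4), _ev("heel_strike", 6),
                   _ev("toe_off", 10)]
                  + [_ev("heel_strike", 3, "right"), _ev("toe_off", 7, "right"),
                     _ev("heel_strike", 9, "right"), _ev("toe_off", 13, "right")])
        gd = G.gait_diagram(events)
        assert (0.0, 4.0) in gd.left and (3.0, 4.0) in gd.overlap

    def test_bipedal_fixture_swing_inside_contralateral_stance(self, gait_bundle):
        gd = G.gait_diagram(gait_bundle.events)
        # every left swing (between stance intervals) lies inside a right stance
        for (s0, s1), (n0, n1) in zip(gd.left[:-1], gd.left[1:]):
            swing = (s1, n0)
            assert any(r0 <= swing[0] and swing[1] <= r1 for r0, r1 in gd.right)

    def test_disjoint_stances_have_empty_overlap(self):
        events = ([_ev("heel_strike", 0), _ev("toe_off", 1), _ev("heel_strike", 4),
                   _ev("toe_off", 5)]
                  + [_ev("heel_strike", 2, "right"), _ev("toe_off", 3, "right"),
                     _ev("heel_strike", 6, "right"), _ev("toe_off", 7, "right")])
        assert G.gait_diagram(events).overlap == []


class TestTwoPhaseCycles:
    def test_power_return_decomposition(self):
        out = G.two_phase_cycles([0.0, 0.14], [0.04])
        assert out == [{"t_start": 0.0, "phase1_duration": pytest.approx(0.04),
                        "phase2_duration": pytest.approx(0.10)}]

    def test_single_entry_yields_no_cycle(self):
        assert G.two_phase_cycles([0.0], []) == []

    def test_mid_before_first_entry_rejected(self):
        with pytest.raises(OrderingError):
            G.two_phase_cycles([1.0, 2.0], [0.5, 1.5])


class TestDetector:
    def test_recovers_ground_truth_events(self, gait_bundle):
        detected = G.detect_events_heuristic(gait_bundle.elements["left_leg"])
        truth = {(ev.type, ev.frame) for ev in gait_bundle.events
                 if ev.side == "left"}
        got = {(ev.type, ev.frame) for ev in detected}
        # every truth event matched within one frame
        for typ, frame in truth:
            assert any(t == typ and abs(f - frame) <= 1 for t, f in got)
        assert len(got) == len(truth)

    def test_constant_height_rejected(self, zigzag_element):
        import numpy as np
        from motionlab.core import PointTrajectory, build_element
        t = np.arange(100.0)
        flat = build_element("flat", [
            PointTrajectory("heel", t, np.column_stack([t, np.zeros(100)])),
            PointTrajectory("toe", t, np.column_stack([t + 1, np.zeros(100)])),
        ])
        with pytest.raises(DetectionError):
            G.detect_events_heuristic(flat)

    def test_detected_events_feed_cycle_computation(self, gait_bundle):
        e = gait_bundle.elements["left_leg"]
        detected = G.detect_events_heuristic(e)
        cycles = G.compute_cycles(e, detected, "left")
        assert cycles[0].stride_length == pytest.approx(7.0, abs=0.1)
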