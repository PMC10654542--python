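import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from escapekit.features import (
    EpochSummary,
    FeatureConfig,
    MalformedLogError,
    classify_outcome,
    detect_escape_initiation,
    escape_speed_stats,
    fruit_picking_rate,
    interrupted_escape,
    min_distances,
    orientation_cosine,
    summarize_epoch,
    time_average_trapezium,
    visual_scanning_rate,
)
from escapekit.simulate import EventLog, TrajectoryRecording


def make_recording(t, head_pos, head_fwd=None, threat=None):
    t = np.asarray(t, float)
    head_pos = np.asarray(head_pos, float)
    n = len(t)
    if head_fwd is None:
        head_fwd = np.tile([0.0, 1.0], (n, 1))
    head_fwd = np.asarray(head_fwd, float)
    if threat is None:
        threat = np.full((n, 2), np.nan)
    return TrajectoryRecording(t, head_pos, head_fwd, head_pos.copy(), head_fwd.copy(), np.asarray(threat, float))


def simple_log(**kw):
    defaults = dict(threat_appearance_time=0.0, epoch_end_time=10.0, outcome="survived")
    defaults.update(kw)
    return EventLog(**defaults)


class TestTrapezium:
    def test_linear_signal(self):
        assert time_average_trapezium([0, 1, 2], [0, 1, 2], (0, 2)) == pytest.approx(1.0)

    def test_hand_integrated_irregular(self):
        # (0+2)/2*1 + (2+2)/2*2 = 5, over length 3
        assert time_average_trapezium([0, 1, 3], [0, 2, 2], (0, 3)) == pytest.approx(5 / 3)

    def test_constant(self):
        assert time_average_trapezium([0, 0.4, 1.1, 2], [7, 7, 7, 7], (0.2, 1.7)) == pytest.approx(7.0)

    def test_insufficient_samples(self):
        assert math.isnan(time_average_trapezium([0.0], [1.0], (0, 1)))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_dense_oracle_for_smooth_signal(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 10, 40))
        t = t[np.concatenate(([True], np.diff(t) > 1e-6))]
        if len(t) < 4:
            return
        v = np.sin(t) + 0.3 * t
        a = float(rng.uniform(t[0], t[-2]))
        b = float(rng.uniform(a + 0.1, t[-1]))
        got = time_average_trapezium(t, v, (a, b))
        # oracle: dense resampling of the piecewise-linear interpolant
        dense_t = np.linspace(a, b, 20001)
        dense_v = np.interp(dense_t, t, v)
        want = np.trapezoid(dense_v, dense_t) / (b - a)
        assert got == pytest.approx(want, abs=1e-6)


class TestOutcome:
    def test_contact(self):
        log = simple_log(contact_time=5.0)
        assert classify_outcome(log) == "virtual_death"

    def test_shelter(self):
        assert classify_outcome(simple_log(shelter_entry_time=4.0)) == "escape_to_shelter"

    def test_timeout(self):
        assert classify_outcome(simple_log()) == "survived"

    def test_magical_force(self):
        assert classify_outcome(simple_log(magical_force_time=2.0)) == "virtual_death"

    def test_multiple_terminal_events_rejected(self):
        with pytest.raises(ValueError):
            EventLog(
                threat_appearance_time=0.0,
                epoch_end_time=10.0,
                outcome="survived",
                contact_time=3.0,
                shelter_entry_time=4.0,
            )


class TestEscapeInitiation:
    def test_stationary_head(self):
        t = np.arange(0, 5, 0.1)
        rec = make_recording(t, np.tile([0.0, 2.5], (len(t), 1)))
        flag, when = detect_escape_initiation(rec, simple_log())
        assert not flag and math.isnan(when)

    def test_step_away_detected(self):
        t = np.arange(0, 6, 0.05)
        pos = np.tile([0.0, 2.5], (len(t), 1))
        moving = t >= 2.0
        pos[moving, 1] = 2.5 - 1.5 * (t[moving] - 2.0)  # walks away at 1.5 m/s
        rec = make_recording(t, pos)
        flag, when = detect_escape_initiation(rec, simple_log(), radius=0.5)
        assert flag
        assert when == pytest.approx(2.0 + 0.5 / 1.5, abs=0.1)

    def test_brief_excursion_rejected(self):
        t = np.arange(0, 6, 0.05)
        pos = np.tile([0.0, 2.5], (len(t), 1))
        out = (t >= 2.0) & (t < 2.1)
        back = (t >= 2.1) & (t < 2.2)
        pos[out, 1] = 2.5 - 6.0 * (t[out] - 2.0)  # 0.6 m out in 0.1 s
        pos[back, 1] = 1.9 + 6.0 * (t[back] - 2.1)
        rec = make_recording(t, pos)
        flag, when = detect_escape_initiation(rec, simple_log(), radius=0.5, min_outward=0.3)
        assert not flag


class TestInterrupted:
    def test_initiated_but_survived(self):
        assert interrupted_escape(True, "survived") is True

    def test_initiated_and_sheltered(self):
        assert interrupted_escape(True, "escape_to_shelter") is False

    def test_not_initiated_is_missing(self):
        assert interrupted_escape(False, "survived") is None


class TestMinDistances:
    def test_fixed_participant_five_meters_from_shelter(self):
        t = np.arange(0, 3, 0.1)
        rec = make_recording(t, np.tile([0.0, 2.5], (len(t), 1)))
        _, d_shelter = min_distances(rec, shelter_position=(0.0, -2.5))
        assert d_shelter == pytest.approx(5.0)

    def test_threat_through_participant(self):
        t = np.array([0.0, 1.0, 2.0])
        pos = np.tile([0.0, 0.0], (3, 1))
        threat = np.array([[0.0, 3.0], [0.0, 0.0], [0.0, -3.0]])
        d_threat, _ = min_distances(make_recording(t, pos, threat=threat))
        assert d_threat == pytest.approx(0.0)

    def test_two_samples(self):
        t = np.array([0.0, 1.0])
        pos = np.zeros((2, 2))
        threat = np.array([[0.0, 3.0], [0.0, 2.0]])
        d_threat, _ = min_distances(make_recording(t, pos, threat=threat))
        assert d_threat == pytest.approx(2.0)

    def test_threat_never_present(self):
        t = np.array([0.0, 1.0])
        d_threat, _ = min_distances(make_recording(t, np.zeros((2, 2))))
        assert math.isnan(d_threat)


class TestSpeedStats:
    def test_constant_speed(self):
        t = np.arange(0, 4, 0.02)
        pos = np.stack([np.zeros_like(t), 2.5 - 2.0 * t], axis=1)
        rec = make_recording(t, pos)
        peak, mean = escape_speed_stats(rec, 0.5, 3.5)
        assert peak == pytest.approx(2.0, abs=1e-6)
        assert mean == pytest.approx(2.0, abs=1e-6)

    def test_two_phase_speed(self):
        # 1 m/s then 3 m/s for equal durations: mean 2, peak 3
        t = np.arange(0, 4.0001, 0.01)
        y = np.where(t <= 2.0, 1.0 * t, 2.0 + 3.0 * (t - 2.0))
        rec = make_recording(t, np.stack([np.zeros_like(t), y], axis=1))
        peak, mean = escape_speed_stats(rec, 0.0, 4.0, smooth_window=0.0)
        assert peak == pytest.approx(3.0, abs=0.05)
        assert mean == pytest.approx(2.0, abs=0.02)

    def test_missing_initiation(self):
        t = np.arange(0, 2, 0.1)
        rec = make_recording(t, np.zeros((len(t), 2)))
        peak, mean = escape_speed_stats(rec, math.nan, 2.0)
        assert math.isnan(peak) and math.isnan(mean)


class TestOrientation:
    def _recording(self, fwd_builder):
        t = np.arange(0, 2, 0.05)
        n = len(t)
        pos = np.zeros((n, 2))
        threat = np.tile([0.0, 5.0], (n, 1))
        fwd = fwd_builder(n)
        return make_recording(t, pos, head_fwd=fwd, threat=threat)

    def test_toward(self):
        rec = self._recording(lambda n: np.tile([0.0, 1.0], (n, 1)))
        assert orientation_cosine(rec, "head", (0, 2)) == pytest.approx(1.0)

    def test_away(self):
        rec = self._recording(lambda n: np.tile([0.0, -1.0], (n, 1)))
        assert orientation_cosine(rec, "head", (0, 2)) == pytest.approx(-1.0)

    def test_perpendicular(self):
        rec = self._recording(lambda n: np.tile([1.0, 0.0], (n, 1)))
        assert orientation_cosine(rec, "head", (0, 2)) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_under_reversal(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 2, 0.05)
        n = len(t)
        ang = rng.uniform(-np.pi, np.pi, n)
        fwd = np.stack([np.sin(ang), np.cos(ang)], axis=1)
        pos = rng.normal(0, 0.5, (n, 2))
        threat = rng.normal(3, 0.5, (n, 2))
        a = make_recording(t, pos, head_fwd=fwd, threat=threat)
        b = make_recording(t, pos, head_fwd=-fwd, threat=threat)
        ca = orientation_cosine(a, "head", (0, 2))
        cb = orientation_cosine(b, "head", (0, 2))
        assert ca == pytest.approx(-cb, abs=1e-9)
        assert -1.0 <= ca <= 1.0


class TestScanning:
    @staticmethod
    def _rotating(t, rate_deg):
        ang = np.radians(rate_deg) * t
        return np.stack([np.sin(ang), np.cos(ang)], axis=1)

    def test_static_head(self):
        t = np.arange(0, 2, 0.05)
        rec = make_recording(t, np.zeros((len(t), 2)))
        assert visual_scanning_rate(rec, "head", (0, 2)) == pytest.approx(0.0)

    def test_constant_rotation(self):
        t = np.arange(0, 2.0001, 1 / 90)
        rec = make_recording(t, np.zeros((len(t), 2)), head_fwd=self._rotating(t, 30.0))
        assert visual_scanning_rate(rec, "head", (0, 2)) == pytest.approx(30.0, rel=1e-6)

    def test_oscillation_counts_path_length(self):
        # +/-10 deg at 1 Hz: cumulative path, not net displacement
        t = np.arange(0, 1.5 + 1e-9, 1 / 900)
        yaw = np.radians(10.0) * np.sin(2 * np.pi * t)
        fwd = np.stack([np.sin(yaw), np.cos(yaw)], axis=1)
        rec = make_recording(t, np.zeros((len(t), 2)), head_fwd=fwd)
        got = visual_scanning_rate(rec, "head", (0, 1.5))
        # oracle: cumulative absolute yaw increments of the generated signal
        want = np.sum(np.abs(np.diff(np.degrees(yaw)))) / 1.5
        assert got == pytest.approx(want, rel=1e-6)

    def test_sampling_robustness(self):
        t1 = np.arange(0, 2.0001, 1 / 90)
        t2 = np.arange(0, 2.0001, 1 / 180)
        r1 = make_recording(t1, np.zeros((len(t1), 2)), head_fwd=self._rotating(t1, 45.0))
        r2 = make_recording(t2, np.zeros((len(t2), 2)), head_fwd=self._rotating(t2, 45.0))
        v1 = visual_scanning_rate(r1, "head", (0, 2))
        v2 = visual_scanning_rate(r2, "head", (0, 2))
        assert abs(v1 - v2) / v1 < 0.01

    def test_gaze_aliases_head(self):
        t = np.arange(0, 2, 1 / 90)
        rec = make_recording(t, np.zeros((len(t), 2)), head_fwd=self._rotating(t, 20.0))
        assert visual_scanning_rate(rec, "gaze", (0, 2)) == visual_scanning_rate(
            rec, "head", (0, 2)
        )


class TestFruitRate:
    def test_three_picks_in_two_seconds(self):
        log = simple_log(fruit_pick_times=[0.5, 1.0, 1.5])
        assert fruit_picking_rate(log, (0, 2)) == pytest.approx(1.5)

    def test_no_picks(self):
        assert fruit_picking_rate(simple_log(), (0, 2)) == pytest.approx(0.0)

    def test_min_duration_window(self):
        picks = list(np.linspace(0.5, 12.0, 14))
        log = simple_log(epoch_end_time=13.0, fruit_pick_times=picks)
        assert fruit_picking_rate(log, (0.0, 12.5)) == pytest.approx(14 / 12.5)


class TestSummarize:
    def test_never_moving_divert_epoch(self, divert_scenario):
        from escapekit.simulate import AgentPolicy, simulate_epoch

        rec, log = simulate_epoch(
            divert_scenario,
            AgentPolicy(escape_target="none"),
            np.random.default_rng(5),
        )
        s = summarize_epoch(rec, log)
        assert s.outcome == "survived"
        assert not s.initiated_escape
        for name in EpochSummary.ESCAPE_FIELDS:
            val = getattr(s, name)
            assert val is None or (isinstance(val, float) and math.isnan(val))

    def test_textbook_escape_all_finite(self, textbook_epoch):
        rec, log = textbook_epoch
        s = summarize_epoch(rec, log)
        assert s.initiated_escape
        for name in ("escape_initiation_time", "peak_speed", "mean_speed",
                     "min_dist_shelter", "min_dist_threat"):
            assert math.isfinite(getattr(s, name))
        for name in ("body_orient_appear", "body_orient_escape",
                     "head_orient_appear", "head_orient_escape"):
            assert -1.0 <= getattr(s, name) <= 1.0

    def test_missingness_contract(self, textbook_epoch):
        rec, log = textbook_epoch
        s = summarize_epoch(rec, log)
        # initiated: none of the escape fields may be missing
        for name in EpochSummary.ESCAPE_FIELDS:
            val = getattr(s, name)
            assert val is not None
            if isinstance(val, float):
                assert math.isfinite(val)

    def test_reproducible_under_seed(self, attack_scenario):
        from escapekit.simulate import AgentPolicy, simulate_epoch

        outs = []
        for _ in range(2):
            rec, log = simulate_epoch(
                attack_scenario, AgentPolicy(), np.random.default_rng(17)
            )
            outs.append(summarize_epoch(rec, log).to_dict())
        assert outs[0] == outs[1]

    def test_no_threat_epoch_uses_reference_time(self):
        from escapekit.simulate import AgentPolicy, simulate_epoch

        rec, log = simulate_epoch(None, AgentPolicy(escape_target="none"), np.random.default_rng(3))
        s = summarize_epoch(rec, log)
        assert 1.0 <= s.reference_time_used <= 11.0
        assert math.isnan(s.min_dist_threat)

    def test_malformed_log(self):
        t = np.arange(0, 2, 0.1)
        rec = make_recording(t, np.zeros((len(t), 2)))
        log = EventLog(threat_appearance_time=None, epoch_end_time=2.0, outcome="survived")
        with pytest.raises(MalformedLogError):
            summarize_epoch(rec, log)
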