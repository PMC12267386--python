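"""Scoring pipeline: classification cutoffs, kinematics, summaries."""

import statistics

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ev, make_log, press_trial, reach_trial
from reachtime.geometry import Vec3
from reachtime.metrics import (
    InsufficientDataError,
    MalformedLogError,
    classify_rt,
    icv,
    rt_diff,
    score_log,
    summarize_task,
)
from reachtime.protocol import ProtocolConfig, build_vr_schedules
from reachtime.simulant import ParticipantParams, simulate_session


class TestClassifyRT:
    @pytest.mark.parametrize(
        "rt, is_go, expected",
        [
            (99.0, True, "anticipation"),
            (99.999, True, "anticipation"),
            (100.0, True, "valid"),  # inclusive lower boundary
            (550.0, True, "valid"),
            (1000.0, True, "valid"),  # inclusive upper boundary
            (1000.001, True, "omission"),
            (1001.0, True, "omission"),
            (None, True, "omission"),
            (300.0, False, "false_alarm"),
            (None, False, "correct_rejection"),
        ],
    )
    def test_boundaries(self, rt, is_go, expected):
        assert classify_rt(rt, is_go, "com_srt") == expected


class TestICV:
    def test_hand_computed(self):
        assert icv([240.0, 250.0, 260.0]) == pytest.approx(10.0 / 250.0)

    def test_constant_series_zero(self):
        assert icv([300.0, 300.0, 300.0]) == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(
        values=st.lists(st.floats(50, 2000), min_size=3, max_size=30),
        c=st.floats(0.1, 10),
    )
    def test_scale_invariance(self, values, c):
        assert icv([c * v for v in values]) == pytest.approx(icv(values), rel=1e-9)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            icv([250.0])


class TestScoreLog:
    def test_reach_trial_arithmetic(self, cal, grid):
        """Onset at base, exit at 300 ms, touch at 500 ms 0.5 m away:
        rt 300, mt 200, displacement 0.5 - 0.028, mv = displacement/0.2 s."""
        b = cal.location_b
        touch_p = b + Vec3(0, 0, 0.5)
        log = make_log(
            cal,
            grid,
            [reach_trial()],
            [
                ev(0.0, "stimulus_onset", task="center"),
                ev(0.0, "controller_sample", position=b.as_tuple()),
                ev(300.0, "base_exit", position=(b + Vec3(0, 0, 0.028)).as_tuple()),
                ev(500.0, "touch", position=touch_p.as_tuple()),
                ev(2000.0, "stimulus_offset"),
            ],
        )
        (rec,) = score_log(log)
        assert rec.rt_ms == 300.0
        assert rec.mt_ms == 200.0
        assert rec.displacement_m == pytest.approx(0.472)
        assert rec.mv_mps == pytest.approx(2.36)
        assert rec.classification == "valid" and rec.touched

    def test_go_trial_without_response_is_omission(self, cal, grid):
        log = make_log(
            cal, grid, [press_trial()],
            [ev(0.0, "stimulus_onset"), ev(260.0, "stimulus_offset")],
        )
        (rec,) = score_log(log)
        assert rec.classification == "omission" and rec.rt_ms is None

    def test_nogo_press_is_false_alarm(self, cal, grid):
        log = make_log(
            cal, grid, [press_trial(task="com_crt", color="blue", is_go=False)],
            [ev(0.0, "stimulus_onset"), ev(210.0, "button_down"), ev(260.0, "stimulus_offset")],
        )
        (rec,) = score_log(log)
        assert rec.classification == "false_alarm"

    def test_valid_rt_without_touch_is_m_omission(self, cal, grid):
        b = cal.location_b
        log = make_log(
            cal, grid, [reach_trial()],
            [
                ev(0.0, "stimulus_onset"),
                ev(0.0, "controller_sample", position=b.as_tuple()),
                ev(350.0, "base_exit", position=(b + Vec3(0.028, 0, 0)).as_tuple()),
                ev(2000.0, "stimulus_offset"),
            ],
        )
        (rec,) = score_log(log)
        assert rec.classification == "valid" and rec.m_omission and not rec.touched

    def test_touch_without_base_exit_rejected(self, cal, grid):
        log = make_log(
            cal, grid, [reach_trial()],
            [
                ev(0.0, "stimulus_onset"),
                ev(400.0, "touch", position=(0, 1.2, 0.5)),
                ev(2000.0, "stimulus_offset"),
            ],
        )
        with pytest.raises(MalformedLogError, match="trial 0"):
            score_log(log)

    def test_pre_onset_base_exit_flags_pause(self, cal, grid):
        b = cal.location_b
        log = make_log(
            cal, grid, [reach_trial()],
            [
                ev(-500.0, "base_exit", position=(b + Vec3(0.03, 0, 0)).as_tuple()),
                ev(0.0, "stimulus_onset"),
                ev(2000.0, "stimulus_offset"),
            ],
        )
        (rec,) = score_log(log)
        assert rec.paused
        summ = summarize_task([rec], "center")
        assert summ.n_trials == 0 and summ.n_paused == 1


class TestSummaries:
    def _quiet_log(self, cal, grid, seed=3):
        params = ParticipantParams(
            lapse_p=0.0, anticipation_p=0.0, false_alarm_p=0.0, miss_touch_p=0.0,
            aim_noise_m=0.0, timing_jitter_ms=0.0, base_jitter_m=0.0,
        )
        cfg = ProtocolConfig(seed=seed)
        return simulate_session(params, build_vr_schedules(cfg), cal, grid, seed=seed)

    def test_partition_of_go_trials(self, cal, grid):
        recs = score_log(self._quiet_log(cal, grid))
        go = [r for r in recs if r.is_go and not r.is_training]
        n_cls = sum(
            r.classification in ("valid", "anticipation", "omission") for r in go
        )
        assert n_cls == len(go)

    def test_mv_identity(self, cal, grid):
        for r in score_log(self._quiet_log(cal, grid)):
            if r.mv_mps is not None:
                assert r.mv_mps == pytest.approx(
                    r.displacement_m / (r.mt_ms / 1000.0), abs=1e-12
                )

    def test_over_600_excluded_from_central_values(self, cal, grid):
        b = cal.location_b
        trials, events = [], []
        t0 = 0.0
        for i, mt in enumerate([200.0, 601.0, 300.0]):
            trials.append(reach_trial(index=i))
            events += [
                ev(t0, "stimulus_onset", trial=i),
                ev(t0, "controller_sample", trial=i, position=b.as_tuple()),
                ev(t0 + 300.0, "base_exit", trial=i,
                   position=(b + Vec3(0.028, 0, 0)).as_tuple()),
                ev(t0 + 300.0 + mt, "touch", trial=i, position=(b + Vec3(0, 0, 0.5)).as_tuple()),
                ev(t0 + 2000.0, "stimulus_offset", trial=i),
            ]
            t0 += 6000.0
        summ = summarize_task(score_log(make_log(cal, grid, trials, events)), "center")
        assert summ.mt.n == 2
        assert summ.mt.mean == pytest.approx(250.0)
        assert summ.over_600_rate == pytest.approx(1 / 3)

    def test_summary_matches_bruteforce_oracle(self, cal, grid):
        """Naive-loop recomputation agrees with summarize_task on a noisy
        simulated session."""
        cfg = ProtocolConfig(seed=11)
        params = ParticipantParams(anticipation_p=0.1, lapse_p=0.1, false_alarm_p=0.3,
                                   miss_touch_p=0.1)
        log = simulate_session(params, build_vr_schedules(cfg), cal, grid, seed=12)
        recs = score_log(log)
        for task in ("press_srt", "press_crt", "center", "spatial", "dynamic"):
            summ = summarize_task(recs, task)
            sel = [r for r in recs if r.task == task and not r.is_training and not r.paused]
            go = [r for r in sel if r.is_go]
            nogo = [r for r in sel if not r.is_go]
            rts = [r.rt_ms for r in sel if r.classification == "valid"]
            mts = [r.mt_ms for r in sel if r.touched and r.mt_ms <= 600.0]
            if rts:
                assert summ.rt.median == pytest.approx(statistics.median(rts))
                assert summ.rt.mean == pytest.approx(statistics.fmean(rts))
            if len(mts) >= 2:
                assert summ.mt.icv == pytest.approx(
                    statistics.stdev(mts) / statistics.fmean(mts)
                )
            if go:
                assert summ.omission_rate == pytest.approx(
                    sum(r.classification == "omission" for r in go) / len(go)
                )
                assert summ.anticipation_rate == pytest.approx(
                    sum(r.classification == "anticipation" for r in go) / len(go)
                )
            if nogo:
                assert summ.false_alarm_rate == pytest.approx(
                    sum(r.classification == "false_alarm" for r in nogo) / len(nogo)
                )
            assert summ.m_omission_rate == pytest.approx(
                sum(r.m_omission for r in sel) / len(sel)
            )

    def test_zero_valid_trials_warns(self, cal, grid):
        log = make_log(
            cal, grid, [press_trial()],
            [ev(0.0, "stimulus_onset"), ev(260.0, "stimulus_offset")],
        )
        summ = summarize_task(score_log(log), "com_srt")
        assert summ.no_valid_warning and summ.rt.median is None


class TestRTDiff:
    def test_published_group_identity(self):
        """The choice-minus-simple difference of the published computer-test
        group medians and means."""
        assert 360.91 - 239.42 == pytest.approx(121.49)
        assert 369.55 - 244.85 == pytest.approx(124.70)

    def test_componentwise_subtraction(self, cal, grid):
        b = cal.location_b
        trials = [press_trial(task="com_srt", index=0)]
        events = [ev(0.0, "stimulus_onset"), ev(239.42, "button_down"),
                  ev(260.0, "stimulus_offset")]
        srt = summarize_task(score_log(make_log(cal, grid, trials, events)), "com_srt")
        trials = [press_trial(task="com_crt", index=0)]
        events = [ev(0.0, "stimulus_onset"), ev(360.91, "button_down"),
                  ev(260.0, "stimulus_offset")]
        crt = summarize_task(score_log(make_log(cal, grid, trials, events)), "com_crt")
        d = rt_diff(crt, srt)
        assert d.diff_median == pytest.approx(121.49)
        assert d.diff_mean == pytest.approx(121.49)

    def test_identity_gives_zero(self, cal, grid):
        trials = [press_trial(task="com_srt", index=0)]
        events = [ev(0.0, "stimulus_onset"), ev(250.0, "button_down"),
                  ev(260.0, "stimulus_offset")]
        s = summarize_task(score_log(make_log(cal, grid, trials, events)), "com_srt")
        d = rt_diff(s, s)
        assert d.diff_median == 0.0 and d.diff_mean == 0.0
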