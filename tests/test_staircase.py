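"""Staircase update rules, the trial loop and the measure estimators."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vibropsych as vp
from vibropsych import ConstantObserver, StaircaseState, TrialRecord, update_staircase
from vibropsych._exceptions import InsufficientDataError


def rec(level=None, correct=True, rt=None, amp=None, i=1):
    return TrialRecord(
        trial_index=i, target_site="LD2",
        response_site="LD2" if correct else "LD3",
        correct=correct, presented_level=level,
        response_time_ms=rt, amplitude_at_press_um=amp,
    )


class TestUpdateRule:
    def test_one_up_one_down(self):
        s = StaircaseState(level=20.0, step=2.0, floor=2.0)
        assert update_staircase(s, True).level == 18.0
        assert update_staircase(s, False).level == 22.0

    def test_two_up_one_down_needs_two_corrects(self):
        s = StaircaseState(level=10.0, step=2.0, floor=2.0, trial_index=11, phase="2u1d")
        s1 = update_staircase(s, True)
        assert (s1.level, s1.consecutive_correct) == (10.0, 1)
        s2 = update_staircase(s1, True)
        assert (s2.level, s2.consecutive_correct) == (8.0, 0)

    def test_two_up_one_down_incorrect_resets(self):
        s = StaircaseState(level=10.0, step=2.0, floor=2.0, trial_index=11,
                           phase="2u1d", consecutive_correct=1)
        s1 = update_staircase(s, False)
        assert (s1.level, s1.consecutive_correct) == (12.0, 0)

    def test_floor_clamp(self):
        s = StaircaseState(level=2.0, step=2.0, floor=2.0)
        assert update_staircase(s, True).level == 2.0

    def test_phase_switches_after_switch_trial(self):
        s = StaircaseState(level=20.0, step=2.0, floor=2.0)
        for _ in range(9):
            s = update_staircase(s, True)
        assert s.phase == "1u1d" and s.trial_index == 10
        s = update_staircase(s, True)
        assert s.phase == "2u1d" and s.trial_index == 11

    def test_inconsistent_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            StaircaseState(level=10.0, step=1.0, floor=1.0, trial_index=3, phase="2u1d")


class TestRunTask:
    def test_error_free_descent_reaches_floor(self, sdt_short):
        result = vp.run_task(sdt_short, ConstantObserver(correct=True),
                             np.random.default_rng(0))
        levels = [t.presented_level for t in result.trials]
        # 20, 18, ..., 4, 2 then held at the floor by the clamp
        assert levels[:10] == [20, 18, 16, 14, 12, 10, 8, 6, 4, 2]
        assert all(a >= b for a, b in zip(levels, levels[1:]))
        assert result.measures["threshold"] == 2.0
        assert result.measures["convergence"] == 5.0

    def test_always_wrong_observer_scores_zero(self, sdt_short):
        result = vp.run_task(sdt_short, ConstantObserver(correct=False),
                             np.random.default_rng(0))
        assert result.measures["convergence"] == 0.0
        levels = [t.presented_level for t in result.trials]
        assert all(a <= b for a, b in zip(levels, levels[1:]))

    def test_seeded_determinism(self, sdt_short):
        obs = vp.ObserverParams()
        a = vp.run_task(sdt_short, obs, np.random.default_rng(99))
        b = vp.run_task(sdt_short, obs, np.random.default_rng(99))
        assert a == b

    def test_threshold_recovery_near_true_value(self, sdt_short):
        # the 2u1d rule targets the 70.7% point, which the calibrated
        # psychometric function puts exactly at the latent threshold
        obs = vp.ObserverParams(theta_sdt_um=6.0, lapse=0.0)
        est = [
            vp.run_task(sdt_short, obs, np.random.default_rng([9, i])).measures["threshold"]
            for i in range(500)
        ]
        assert abs(np.mean(est) - 6.0) < 1.5

    def test_ddt_amplitude_at_press(self):
        spec = next(s for s in vp.default_battery("short") if s.task_id == "dDT")
        obs = vp.ObserverParams(theta_ddt_um=8.0, motor_delay_s=0.2, ddt_trial_sd_um=0.0)
        result = vp.run_task(spec, obs, np.random.default_rng(1))
        # amplitude keeps ramping at 2 um/s during the 0.2-s motor delay
        for t in result.trials:
            assert t.amplitude_at_press_um == pytest.approx(8.4)

    def test_rt_tasks_record_times_not_levels(self):
        spec = next(s for s in vp.default_battery("short") if s.task_id == "sRT")
        result = vp.run_task(spec, vp.ObserverParams(), np.random.default_rng(3))
        assert all(t.presented_level is None for t in result.trials)
        assert all(t.response_time_ms > 0 for t in result.trials)
        assert len(result.trials) == spec.n_trials

    def test_scripted_observer_rejected_for_ddt(self):
        spec = next(s for s in vp.default_battery("short") if s.task_id == "dDT")
        with pytest.raises(vp.ConfigurationError):
            vp.run_task(spec, ConstantObserver(True), np.random.default_rng(0))

    @settings(deadline=None, max_examples=25)
    @given(
        start=st.integers(5, 40),
        step=st.integers(1, 4),
    )
    def test_error_free_levels_nonincreasing(self, start, step):
        spec = dataclasses.replace(
            next(s for s in vp.default_battery("short") if s.task_id == "sDT"),
            initial_level=float(start * step), step_size=float(step),
            floor_level=float(step),
        )
        result = vp.run_task(spec, ConstantObserver(correct=True), np.random.default_rng(0))
        levels = [t.presented_level for t in result.trials]
        assert all(a >= b for a, b in zip(levels, levels[1:]))
        # descent takes (initial-floor)/step 1u1d steps, then two trials per step
        n_steps = start - 1
        bound = min(n_steps, 10) + 2 * max(n_steps - 10, 0) + 1
        if bound <= spec.n_trials:
            assert min(levels) == spec.floor_level


class TestEstimators:
    @pytest.mark.parametrize(
        "levels, expected",
        [([4, 6, 4, 6, 4], 4.8), ([10, 10, 10, 10, 10], 10.0), ([1, 2, 3, 4, 5, 6, 7], 5.0)],
    )
    def test_threshold_is_mean_of_last_five(self, levels, expected):
        trials = [rec(level=float(v), i=i) for i, v in enumerate(levels, 1)]
        assert vp.estimate_threshold(trials) == pytest.approx(expected)

    def test_threshold_needs_five_trials(self):
        with pytest.raises(InsufficientDataError):
            vp.estimate_threshold([rec(level=1.0)] * 4)

    def test_rt_median(self):
        trials = [rec(rt=v, i=i) for i, v in enumerate([200, 210, 400], 1)]
        assert vp.estimate_rt(trials) == 210

    def test_rt_median_correct_only(self):
        trials = [rec(rt=300, correct=True), rec(rt=900, correct=False), rec(rt=500, correct=True)]
        assert vp.estimate_rt(trials, correct_only=True) == 400
        assert vp.estimate_rt(trials, correct_only=False) == 500

    def test_rt_single_trial(self):
        assert vp.estimate_rt([rec(rt=250)]) == 250

    def test_rt_no_qualifying_trials(self):
        with pytest.raises(InsufficientDataError):
            vp.estimate_rt([rec(rt=100, correct=False)], correct_only=True)

    def test_isv_constant_times(self):
        with pytest.warns(UserWarning, match="MAD"):
            assert vp.estimate_isv([rec(rt=200.0)] * 3) == 0.0

    def test_isv_removes_outlier_then_sd(self):
        trials = [rec(rt=v) for v in (190.0, 200.0, 210.0, 1000.0)]
        assert vp.estimate_isv(trials) == pytest.approx(10.0)

    def test_isv_scale_homogeneity(self):
        base = [rec(rt=v) for v in (150.0, 200.0, 260.0, 310.0)]
        doubled = [rec(rt=2 * t.response_time_ms) for t in base]
        assert vp.estimate_isv(doubled) == pytest.approx(2 * vp.estimate_isv(base))

    def test_ddt_mean_over_correct_trials(self):
        trials = [rec(amp=8.4, correct=True), rec(amp=8.4, correct=True)]
        assert vp.estimate_ddt(trials) == pytest.approx(8.4)
        trials = [rec(amp=8.0, correct=True), rec(amp=10.0, correct=True),
                  rec(amp=50.0, correct=False)]
        assert vp.estimate_ddt(trials) == pytest.approx(9.0)

    def test_ddt_no_correct_trials(self):
        with pytest.raises(InsufficientDataError):
            vp.estimate_ddt([rec(amp=5.0, correct=False)])

    @pytest.mark.parametrize(
        "pattern, expected",
        [([True] * 5, 5), ([False] * 5, 0), ([True, False, True, True, False], 3)],
    )
    def test_convergence_counts_final_five(self, pattern, expected):
        trials = [rec(level=1.0, correct=True, i=1)] * 3 + [
            rec(level=1.0, correct=c, i=i) for i, c in enumerate(pattern, 4)
        ]
        assert vp.convergence_score(trials) == expected


class TestTruncation:
    def test_truncation_to_full_length_is_identity(self, sdt_short):
        result = vp.run_task(sdt_short, vp.ObserverParams(), np.random.default_rng(5))
        assert vp.truncate_long(result, len(result.trials)) == result

    def test_threshold_recomputed_from_retained_trials(self, sdt_short):
        import dataclasses as dc

        spec = dc.replace(sdt_short, version="long", n_trials=48)
        result = vp.run_task(spec, vp.ObserverParams(), np.random.default_rng(5))
        trunc = vp.truncate_long(result, 24)
        last5 = [t.presented_level for t in result.trials[19:24]]
        assert trunc.measures["threshold"] == pytest.approx(np.mean(last5))
        assert trunc.measures["convergence"] == sum(t.correct for t in result.trials[19:24])

    def test_error_free_truncated_threshold_not_lower(self, sdt_short):
        import dataclasses as dc

        spec = dc.replace(sdt_short, version="long", n_trials=48)
        result = vp.run_task(spec, ConstantObserver(correct=True), np.random.default_rng(0))
        trunc = vp.truncate_long(result, 24)
        assert trunc.measures["threshold"] >= result.measures["threshold"]

    def test_overlong_truncation_rejected(self, sdt_short):
        result = vp.run_task(sdt_short, vp.ObserverParams(), np.random.default_rng(5))
        with pytest.raises(ValueError):
            vp.truncate_long(result, 999)
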