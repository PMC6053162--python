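"""Detection/staging rules: boundary semantics and oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from akih.criteria import (ScrContext, UndecidableContext, build_context,
                           detect_aki, find_episodes, initial_scr,
                           label_horizon, label_window, recent_scr,
                           stage_episode, stage_from_predicted, DAY)

H = 24.0  # hours per day


def ctx(initial=None, recent=None, t=0.0):
    return ScrContext(t=t, initial_scr=initial, recent_scr=recent)


class TestReferenceValues:
    def test_initial_is_min_of_both_candidates(self):
        # scr_a (first within +/-2 months) = 1.2, scr_b (first after) = 1.0
        times = np.array([-10 * DAY, 5 * DAY])
        values = np.array([1.2, 1.0])
        assert initial_scr(times, values, 0.0) == 1.0

    def test_initial_single_candidate(self):
        times, values = np.array([5 * DAY]), np.array([0.9])
        assert initial_scr(times, values, 0.0) == 0.9

    def test_initial_absent_when_no_qualifying_measurement(self):
        # only a measurement before the -2-month bound
        times, values = np.array([-70 * DAY]), np.array([1.0])
        assert initial_scr(times, values, 0.0) is None

    def test_initial_window_bound_is_61_days_inclusive(self):
        times, values = np.array([-61 * DAY]), np.array([1.4])
        assert initial_scr(times, values, 0.0) == 1.4

    def test_scr_b_unbounded_after_registration(self):
        times, values = np.array([400 * DAY]), np.array([0.8])
        assert initial_scr(times, values, 0.0) == 0.8

    def test_recent_is_window_minimum(self):
        t = 100 * DAY
        times = np.array([t - 10 * DAY, t - 5 * DAY])
        values = np.array([1.1, 1.4])
        assert recent_scr(times, values, t) == 1.1

    def test_recent_excludes_measurement_at_22_days(self):
        t = 100 * DAY
        assert recent_scr(np.array([t - 22 * DAY]), np.array([1.0]), t) is None

    def test_recent_excludes_current_instant(self):
        t = 100 * DAY
        assert recent_scr(np.array([t]), np.array([1.0]), t) is None

    def test_recent_includes_start_boundary(self):
        t = 100 * DAY
        assert recent_scr(np.array([t - 21 * DAY]), np.array([0.9]), t) == 0.9


class TestDetection:
    @pytest.mark.parametrize("current,initial,recent,expect", [
        (1.6, 1.0, None, True),    # ratio 1.6 > 1.5
        (0.75, 0.5, None, False),  # ratio exactly 1.5: strict, no detection
        (1.5, 1.0, None, True),    # ratio at the edge but increment 0.5 > 0.3
        (1.35, 1.0, None, True),   # increment 0.35 > 0.3
        (1.30, 1.0, None, False),  # increment exactly 0.3: strict
        (1.2, None, 1.0, False),
        (1.45, 2.0, 1.0, True),    # recent triggers even though initial does not
    ])
    def test_detection_rules(self, current, initial, recent, expect):
        detected, _ = detect_aki(current, ctx(initial, recent))
        assert detected is expect

    def test_detection_fixes_baseline_to_trigger(self):
        detected, updated = detect_aki(1.6, ctx(initial=1.0))
        assert detected and updated.baseline_scr == 1.0
        assert updated.baseline_source == "initial"

    def test_tie_rule_picks_smaller_comparator(self):
        # both references trigger; the smaller maximises severity
        detected, updated = detect_aki(3.0, ctx(initial=1.2, recent=0.9))
        assert detected and updated.baseline_scr == 0.9
        assert updated.baseline_source == "recent"

    def test_undecidable_context_raises(self):
        with pytest.raises(UndecidableContext):
            detect_aki(2.0, ctx())


class TestStaging:
    @pytest.mark.parametrize("values,baseline,stage", [
        ([2.1, 2.5], 1.0, 2),   # max ratio 2.5 in [2, 3)
        ([4.1], 2.8, 3),        # absolute >= 4.0
        ([1.45], 1.0, 1),       # ratio-stage 0 but increment 0.45 > 0.3
        ([3.0], 1.0, 3),        # ratio exactly 3.0 inclusive
        ([2.0], 1.0, 2),        # band edge 2.0 inclusive
        ([1.5], 1.0, 1),        # band edge 1.5 inclusive
        ([4.0], 2.8, 3),        # absolute edge 4.0 inclusive
        ([1.2], 1.0, 0),        # nothing (direct staging of a quiet window)
    ])
    def test_stage_bands(self, values, baseline, stage):
        assert stage_episode(values, baseline)["stage"] == stage

    def test_stage_is_max_of_ratio_and_increment_stages(self):
        out = stage_episode([1.45], 1.0)
        assert out["stage_by_ratio"] == 0
        assert out["stage_by_increment"] == 1
        assert out["stage"] == 1

    def test_empty_window_fatal(self):
        with pytest.raises(ValueError):
            stage_episode([], 1.0)


class TestLabelWindow:
    def test_quiet_horizon_is_stage_zero(self):
        assert label_horizon([1.1, 1.2], 1.0, None) == 0

    def test_stage_from_first_trigger_onward(self):
        # first trigger 2.2; max from there 2.2 -> stage 2
        assert label_horizon([1.2, 2.2, 1.8], 1.0, None) == 2

    def test_values_before_first_trigger_ignored_for_staging(self):
        # 3.5 precedes the window start only if it triggers -- here it does,
        # so staging sees the max
        assert label_horizon([3.5, 1.2], 1.0, None) == 3

    def test_label_window_slices_horizon_half_open(self):
        t = 0.0
        times = np.array([t, t + 1.0, t + 14 * DAY - 1, t + 14 * DAY])
        values = np.array([1.0, 2.2, 1.0, 9.9])
        c = ctx(initial=1.0, t=t)
        # measurement at exactly t+14d is outside the horizon
        assert label_window(times, values, t, c) == 2

    def test_current_measurement_not_in_own_horizon(self):
        times = np.array([0.0, 5 * DAY])
        values = np.array([5.0, 1.0])
        assert label_window(times, values, 0.0, ctx(initial=1.0, t=0.0)) == 0


class TestStageFromPredicted:
    @pytest.mark.parametrize("pred,initial,expect", [
        (2.2, 1.0, 2),
        (1.2, 1.0, 0),
        (4.5, 3.5, 3),   # detection via increment 1.0; absolute >= 4.0 rule
    ])
    def test_examples(self, pred, initial, expect):
        assert stage_from_predicted(pred, ctx(initial=initial)) == expect

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(ValueError):
            stage_from_predicted(-0.1, ctx(initial=1.0))

    @given(st.floats(0.2, 10.0), st.floats(0.3, 3.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_prediction(self, pred, baseline):
        c = ctx(initial=baseline)
        s1 = stage_from_predicted(pred, c)
        s2 = stage_from_predicted(pred + 0.25, c)
        assert s2 >= s1


def brute_force_label(values, baseline):
    """Independent transcription of the printed rules (initial-only context)."""
    eps = 1e-9  # decimal-intent guard, same convention as the engine
    first = None
    for i, v in enumerate(values):
        if v > 1.5 * baseline + eps or v - baseline > 0.3 + eps:
            first = i
            break
    if first is None:
        return 0
    window = values[first:]
    ratios = [v / baseline for v in window]
    increments = [v - baseline for v in window]
    if max(ratios) >= 3.0 - eps or max(window) >= 4.0 - eps:
        return 3
    r = max(ratios)
    stage_ratio = (3 if r >= 3.0 - eps else 2 if r >= 2.0 - eps
                   else 1 if r >= 1.5 - eps else 0)
    stage_inc = 1 if max(increments) > 0.3 + eps else 0
    return max(stage_ratio, stage_inc)


class TestOracleAgreement:
    def test_randomised_series_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            n = rng.integers(1, 6)
            values = np.round(rng.uniform(0.4, 5.0, n), 2).tolist()
            baseline = round(float(rng.uniform(0.5, 3.0)), 2)
            assert label_horizon(values, baseline, None) == \
                brute_force_label(values, baseline)

    def test_two_reference_context_uses_either_trigger(self):
        # initial misses, recent triggers: label must reflect recent
        assert label_horizon([1.4], 2.0, 1.0) == 1
        # stage uses the triggering (smaller) reference as baseline
        assert label_horizon([2.1], 2.0, 1.0) == 2


class TestEpisodeScan:
    def test_single_episode_detected_and_staged(self):
        # baseline 1.0 for 30 days, spike to 2.5, recovery
        times = np.arange(0, 60) * DAY
        values = np.full(60, 1.0)
        values[30:33] = [1.8, 2.5, 1.6]
        eps = find_episodes(times, values, registration_h=0.0)
        assert len(eps) == 1
        assert eps[0].stage == 2
        assert eps[0].baseline_scr == 1.0

    def test_quiet_series_has_no_episode(self):
        times = np.arange(0, 40) * DAY
        values = 1.0 + 0.05 * np.sin(times / 200.0)
        assert find_episodes(times, values, 0.0) == []

    def test_refractory_groups_one_event(self):
        times = np.arange(0, 30) * DAY
        values = np.full(30, 1.0)
        values[10:14] = 2.0  # four consecutive triggering values
        eps = find_episodes(times, values, 0.0)
        assert len(eps) == 1
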