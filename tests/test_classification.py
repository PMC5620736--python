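"""Activity levels, the matching matrix and the behaviour rules."""

from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bms import (
    ActivityLevel,
    ClassifierState,
    Label,
    State,
    activity_level,
    activity_match,
    classify,
    expected_room,
    sampled_global_activity,
    stay_state,
    weighted_global_activity,
)
from bms.classification import UNMODELLED
from bms.events import GridCell, TimeGrid, default_layout
from bms.learning import empty_model


class TestActivityLevel:
    def test_maximum_is_very_high(self):
        assert activity_level(2.0, 2.0) is ActivityLevel.VERY_HIGH

    def test_zero_is_very_low(self):
        assert activity_level(0.0, 2.0) is ActivityLevel.VERY_LOW

    def test_half_of_max_is_medium(self):
        assert activity_level(1.0, 2.0) is ActivityLevel.MEDIUM

    def test_degenerate_max_maps_everything_very_low(self):
        assert activity_level(5.0, 0.0) is ActivityLevel.VERY_LOW

    def test_band_edges(self):
        assert activity_level(0.2, 1.0) is ActivityLevel.LOW
        assert activity_level(0.8, 1.0) is ActivityLevel.VERY_HIGH
        assert activity_level(0.7999, 1.0) is ActivityLevel.HIGH


# The published matching matrix, rows = sampled level, columns = weighted
# level, both ordered VeryHigh, High, Medium, Low, VeryLow.  N = Normal,
# A = Abnormal.
MATCH_MATRIX = [
    "NNAAA",
    "NNNAA",
    "ANNNA",
    "AANNN",
    "AAANN",
]
ORDER = [
    ActivityLevel.VERY_HIGH,
    ActivityLevel.HIGH,
    ActivityLevel.MEDIUM,
    ActivityLevel.LOW,
    ActivityLevel.VERY_LOW,
]


class TestActivityMatch:
    def test_equal_levels_match(self):
        assert activity_match(ActivityLevel.VERY_HIGH, ActivityLevel.VERY_HIGH) == "Normal"

    def test_two_bands_apart_mismatch(self):
        assert activity_match(ActivityLevel.VERY_HIGH, ActivityLevel.MEDIUM) == "Abnormal"

    def test_reproduces_full_matching_matrix(self):
        for i, s_level in enumerate(ORDER):
            for j, w_level in enumerate(ORDER):
                expected = "Normal" if MATCH_MATRIX[i][j] == "N" else "Abnormal"
                assert activity_match(w_level, s_level) == expected, (s_level, w_level)


class TestWeightedGlobalActivity:
    @pytest.fixture()
    def model(self):
        model = empty_model(default_layout(), TimeGrid(60), datetime(2024, 1, 1), 1)
        cur, prev = model.cells[GridCell(0, 4)], model.cells[GridCell(0, 3)]
        cur.obs[0] = 120  # AG = 2 events/min over the hour
        prev.obs[0] = 240  # AG = 4
        return model

    def test_halfway_blend(self, model):
        assert weighted_global_activity(model, datetime(2024, 1, 1, 4, 30)) == pytest.approx(3.0)

    def test_interval_start_weights_previous(self, model):
        w = weighted_global_activity(model, datetime(2024, 1, 1, 4, 0, 1))
        assert w == pytest.approx(4.0, abs=0.01)

    def test_interval_end_weights_current(self, model):
        assert weighted_global_activity(model, datetime(2024, 1, 1, 5, 0)) == pytest.approx(2.0)

    def test_wraps_across_midnight(self, model):
        model.cells[GridCell(6, 23)].obs[0] = 60  # Sunday (23-24], AG = 1
        w = weighted_global_activity(model, datetime(2024, 1, 1, 0, 30))
        assert w == pytest.approx(0.5)


class TestSampledGlobalActivity:
    def test_no_recent_observations(self):
        assert sampled_global_activity([], datetime(2024, 1, 1, 12), 60) == 0.0

    def test_sixty_in_trailing_hour(self):
        now = datetime(2024, 1, 1, 12)
        ts = [now - timedelta(minutes=m) for m in range(60)]
        assert sampled_global_activity(ts, now, 60) == pytest.approx(1.0)

    def test_matches_brute_force_window_count(self):
        now = datetime(2024, 1, 1, 12)
        ts = [now - timedelta(minutes=3 * m, seconds=17) for m in range(60)]
        expected = sum(1 for t in ts if (now - t).total_seconds() <= 3600) / 60
        assert sampled_global_activity(ts, now, 60) == pytest.approx(expected)


class TestStayState:
    @pytest.fixture()
    def model(self, model_a):
        return model_a

    def test_zero_stay_is_normal(self, model):
        assert stay_state(0.0, model, "Bedroom", 0) == "Normal"

    def test_boundary_equal_is_high(self, model):
        longest = model.longest_cs("Bedroom", 0)
        assert longest > 0
        assert stay_state(longest, model, "Bedroom", 0) == "High"
        assert stay_state(longest - 0.1, model, "Bedroom", 0) == "Normal"

    def test_room_never_seen_is_high_immediately(self, model):
        weekday = 0
        assert model.longest_cs("Garage", weekday) == 0.0
        assert stay_state(0.0, model, "Garage", weekday) == "High"


class TestExpectedRoom:
    def test_sleeping_hours_expect_bedroom(self, model_a):
        assert expected_room(model_a, datetime(2024, 1, 29, 4, 25)) == "Bedroom"

    def test_unmodelled_cell_sentinel(self):
        model = empty_model(default_layout(), TimeGrid(60), datetime(2024, 1, 1), 1)
        assert expected_room(model, datetime(2024, 1, 1, 4, 30)) == UNMODELLED

    def test_tie_breaks_by_room_order(self):
        model = empty_model(default_layout(), TimeGrid(60), datetime(2024, 1, 1), 1)
        cell = model.cells[GridCell(0, 4)]
        cell.ts[cell.rooms.index("Bathroom")] = 30.0
        cell.ts[cell.rooms.index("Kitchen")] = 30.0
        assert expected_room(model, datetime(2024, 1, 1, 4, 30)) == "Bathroom"


def state(**kw) -> ClassifierState:
    defaults = dict(
        z=State.ABNORMAL,
        s="Normal",
        w="Normal",
        sag_level=ActivityLevel.MEDIUM,
        detected_room="Livingroom",
        expected="Livingroom",
        w_ag=0.1,
        s_ag=0.1,
    )
    defaults.update(kw)
    return ClassifierState(**defaults)


class TestClassifyRules:
    def test_normal_automaton_state_gates_everything(self):
        label, _ = classify(state(z=State.NORMAL, detected_room="Bedroom", s="High"))
        assert label is Label.NORMAL

    def test_extended_bedroom_stay_is_oversleeping(self):
        label, _ = classify(state(detected_room="Bedroom", s="High"))
        assert label is Label.OVER_SLEEPING

    def test_kitchen_during_sleeping_time_is_lesssleeping(self):
        label, _ = classify(
            state(z=State.POTENTIAL, detected_room="Kitchen", expected="Bedroom")
        )
        assert label is Label.LESS_SLEEPING

    def test_outside_during_sleeping_time_is_lesssleeping(self):
        label, _ = classify(
            state(z=State.POTENTIAL, detected_room="Outside", expected="Bedroom")
        )
        assert label is Label.LESS_SLEEPING

    def test_long_outside_stay_is_notbackhome(self):
        label, _ = classify(state(detected_room="Outside", s="High"))
        assert label is Label.NOT_BACK_HOME

    def test_motionless_overlong_stay_in_store_is_dead(self):
        label, _ = classify(
            state(
                detected_room="Store",
                s="High",
                w="Abnormal",
                sag_level=ActivityLevel.VERY_LOW,
            )
        )
        assert label is Label.DEAD

    def test_dead_requires_confirmed_abnormal_state(self):
        label, note = classify(
            state(
                z=State.POTENTIAL,
                detected_room="Store",
                s="High",
                w="Abnormal",
                sag_level=ActivityLevel.VERY_LOW,
            )
        )
        assert label is Label.NORMAL
        assert note == "unclassified deviation"

    def test_unexplained_deviation_is_noted(self):
        label, note = classify(state())
        assert label is Label.NORMAL
        assert note == "unclassified deviation"

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        z=st.sampled_from(list(State)),
        s=st.sampled_from(["Normal", "High"]),
        w=st.sampled_from(["Normal", "Abnormal"]),
        sag_level=st.sampled_from(list(ActivityLevel)),
        detected=st.sampled_from(["Bedroom", "Kitchen", "Store", "Outside"]),
        expected=st.sampled_from(["Bedroom", "Livingroom", UNMODELLED]),
    )
    def test_no_anomaly_label_while_automaton_normal(self, z, s, w, sag_level, detected, expected):
        label, _ = classify(
            state(z=z, s=s, w=w, sag_level=sag_level, detected_room=detected, expected=expected)
        )
        if z is State.NORMAL:
            assert label is Label.NORMAL
        if label is Label.DEAD:
            assert z is State.ABNORMAL
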