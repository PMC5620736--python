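"""Model construction: transition matrices, activity rates, continuous stays."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from bms import (
    BehaviourModel,
    LearningWindow,
    Observation,
    Stay,
    TimeGrid,
    accumulate_stays,
    build_model,
    continuous_stays,
    empty_model,
    generate,
    profile_a,
)
from bms.learning import ModelCell
from bms.events import GridCell


def make_cell(rooms, ts, m=None, obs=None, n_days=1, delta_t=60):
    cell = ModelCell.empty(GridCell(0, 4), tuple(rooms), delta_t, n_days)
    cell.ts = np.asarray(ts, dtype=float)
    if m is not None:
        cell.m = np.asarray(m, dtype=np.int64)
    if obs is not None:
        cell.obs = np.asarray(obs, dtype=np.int64)
    return cell


class TestAccumulateStays:
    def test_no_stays_leaves_ts_zero(self, layout, grid):
        model = empty_model(layout, grid, datetime(2024, 1, 1), 1)
        accumulate_stays([], model)
        assert all(c.total_stay == 0 for c in model.cells.values())

    def test_single_piece_full_hour(self, layout, grid):
        model = empty_model(layout, grid, datetime(2024, 1, 1), 1)
        accumulate_stays([Stay("Bedroom", datetime(2024, 1, 1, 4), datetime(2024, 1, 1, 5))], model)
        cell = model.cells[GridCell(0, 4)]
        assert cell.ts[cell.rooms.index("Bedroom")] == 60.0

    def test_four_mondays_average_to_45_minutes(self, layout, grid):
        # bedroom stays of 60, 60, 30, 30 min in Monday (4-5] over a 4-week window
        model = empty_model(layout, grid, datetime(2024, 1, 1), 4)
        for week, minutes in enumerate([60, 60, 30, 30]):
            start = datetime(2024, 1, 1, 4) + timedelta(weeks=week)
            accumulate_stays([Stay("Bedroom", start, start + timedelta(minutes=minutes))], model)
        cell = model.cells[GridCell(0, 4)]
        assert cell.ts_mean[cell.rooms.index("Bedroom")] == pytest.approx(45.0)

    def test_stay_outside_window_rejected(self, layout, grid):
        model = empty_model(layout, grid, datetime(2024, 1, 1), 1)
        with pytest.raises(ValueError, match="window"):
            accumulate_stays(
                [Stay("Bedroom", datetime(2024, 2, 1, 4), datetime(2024, 2, 1, 5))], model
            )


class TestTransitionProbabilities:
    def test_whole_interval_in_one_room_gives_probability_one(self):
        cell = make_cell(["A", "B", "C"], ts=[60, 0, 0])
        assert cell.self_transition_prob("A") == 1.0
        assert cell.self_transition_prob("B") == 0.0

    def test_forced_arithmetic_36_of_60(self):
        cell = make_cell(["A", "B"], ts=[36, 24])
        assert cell.self_transition_prob("A") == pytest.approx(0.6)

    def test_stay_probabilities_sum_to_one(self, model_a):
        for cell in model_a.cells.values():
            if not cell.unmodelled:
                assert cell.stay_probs().sum() == pytest.approx(1.0, abs=1e-9)

    def test_off_diagonal_mass_split_by_transition_counts(self):
        # P^{A,A} = 0.4, exits 3:1 towards B -> 0.45 and 0.15
        cell = make_cell(
            ["A", "B", "C"],
            ts=[24, 20, 16],
            m=[[5, 3, 1], [0, 0, 0], [0, 0, 0]],
        )
        assert cell.transition_prob("A", "B") == pytest.approx(0.45)
        assert cell.transition_prob("A", "C") == pytest.approx(0.15)

    def test_rows_sum_to_one_for_observed_rooms(self, model_a):
        for cell in model_a.cells.values():
            matrix = cell.matrix()
            for i, room in enumerate(cell.rooms):
                expected = 1.0 if cell.ts[i] > 0 else 0.0
                assert matrix[i].sum() == pytest.approx(expected, abs=1e-9)

    def test_matrix_matches_symbolic_recomputation(self):
        rng = np.random.default_rng(5)
        rooms = ["A", "B", "C", "D"]
        for _ in range(20):
            ts = rng.uniform(0, 30, size=4)
            ts[rng.integers(0, 4)] = 0.0  # always one unobserved room
            m = rng.integers(0, 6, size=(4, 4))
            cell = make_cell(rooms, ts=ts, m=m)
            got = cell.matrix()
            for i in range(4):
                if ts[i] == 0:
                    assert not got[i].any()
                    continue
                p_ii = ts[i] / ts.sum()
                exits = m[i].astype(float).copy()
                exits[i] = 0
                if exits.sum() == 0:
                    assert got[i, i] == pytest.approx(1.0)
                else:
                    assert got[i, i] == pytest.approx(p_ii)
                    for j in range(4):
                        if j != i:
                            assert got[i, j] == pytest.approx(
                                (1 - p_ii) * m[i, j] / exits.sum()
                            )

    def test_room_without_exits_folds_mass_into_diagonal(self):
        cell = make_cell(["A", "B"], ts=[36, 24], m=[[4, 0], [0, 0]])
        assert cell.matrix()[0].sum() == pytest.approx(1.0)
        assert cell.matrix()[0, 0] == 1.0


class TestActivityRates:
    def test_global_activity_counts_all_observations(self):
        cell = make_cell(["A", "B"], ts=[30, 30], obs=[80, 40])
        assert cell.global_activity() == pytest.approx(2.0)

    def test_inter_room_excludes_self_transitions(self):
        # observation sequence A,B,A,B -> transitions AB, BA, AB
        cell = make_cell(["A", "B"], ts=[30, 30], m=[[0, 2], [1, 0]], obs=[2, 2])
        assert cell.inter_room_activity() == pytest.approx(3 / 60)

    def test_intra_room_rate(self):
        cell = make_cell(["A", "B"], ts=[30, 30], obs=[30, 0])
        assert cell.intra_room_activity("A") == pytest.approx(0.5)
        assert cell.intra_room_activity("B") == 0.0

    def test_identities_on_learned_model(self, model_a):
        for cell in model_a.cells.values():
            ag = cell.global_activity()
            aa_sum = sum(cell.intra_room_activity(r) for r in cell.rooms)
            assert aa_sum == pytest.approx(ag, abs=1e-9)
            assert cell.inter_room_activity() <= ag + 1e-12


class TestContinuousStays:
    def stays(self, spec):
        t = datetime(2024, 1, 1, 4)
        out = []
        for room, minutes in spec:
            out.append(Stay(room, t, t + timedelta(minutes=minutes)))
            t += timedelta(minutes=minutes)
        return out

    def test_runs_merge_and_break(self):
        profiles = continuous_stays(
            self.stays([("Bedroom", 30), ("Bedroom", 40), ("Kitchen", 10), ("Bedroom", 20)])
        )
        monday = profiles[0]
        assert monday.cs_list["Bedroom"] == [70.0, 20.0]
        assert monday.longest_cs("Bedroom") == 70.0
        assert monday.cs_list["Kitchen"] == [10.0]

    def test_single_stay_is_its_own_run(self):
        profiles = continuous_stays(self.stays([("Bedroom", 25)]))
        assert profiles[0].cs_list["Bedroom"] == [25.0]

    def test_zero_duration_interruption_breaks_run(self):
        profiles = continuous_stays(
            self.stays([("Bedroom", 30), ("Bathroom", 0), ("Bedroom", 30)])
        )
        assert profiles[0].cs_list["Bedroom"] == [30.0, 30.0]

    def test_run_credited_to_day_it_started(self):
        stays = [
            Stay("Bedroom", datetime(2024, 1, 1, 23), datetime(2024, 1, 2, 7)),
        ]
        profiles = continuous_stays(stays)
        assert profiles[0].cs_list["Bedroom"] == [480.0]  # Monday, not Tuesday
        assert profiles[1].cs_list == {}

    def test_unseen_room_has_zero_expected_longest_stay(self):
        profiles = continuous_stays(self.stays([("Bedroom", 30)]))
        assert profiles[0].longest_cs("Store") == 0.0


class TestSlidingWindow:
    def test_update_equals_batch_rebuild(self, layout):
        stream = generate(profile_a(), layout, start=datetime(2024, 1, 1), weeks=6, seed=3)
        window = LearningWindow(layout=layout, length_weeks=4, shift_weeks=1)
        window.initialise(stream, start=datetime(2024, 1, 1))
        new_week = [o for o in stream if o.ts >= datetime(2024, 1, 29)]
        updated = window.update(new_week)
        batch = build_model(
            stream, layout, window_start=datetime(2024, 1, 8), window_weeks=4
        )
        for cell in updated.cells:
            assert np.array_equal(updated.cells[cell].ts, batch.cells[cell].ts)
            assert np.array_equal(updated.cells[cell].m, batch.cells[cell].m)
            assert np.array_equal(updated.cells[cell].obs, batch.cells[cell].obs)
        for d in range(7):
            assert updated.day_profiles[d].cs_list == batch.day_profiles[d].cs_list

    def test_shift_with_empty_week_keeps_remaining_weeks(self, layout, stream_a):
        window = LearningWindow(layout=layout, length_weeks=4, shift_weeks=1)
        window.initialise(stream_a, start=datetime(2024, 1, 1))
        model = window.update([])
        assert model.window_start == datetime(2024, 1, 8)
        # last week of the window is empty: Monday cells built from 3 weeks of data
        assert all(o.ts < model.window_end for o in window.buffer)

    def test_shift_cannot_exceed_length(self, layout):
        with pytest.raises(ValueError):
            LearningWindow(layout=layout, length_weeks=2, shift_weeks=3)


class TestSerialisation:
    def test_json_round_trip_preserves_model(self, model_a):
        clone = BehaviourModel.from_json(model_a.to_json())
        assert clone.window_start == model_a.window_start
        assert clone.rooms == model_a.rooms
        for key, cell in model_a.cells.items():
            assert np.array_equal(clone.cells[key].ts, cell.ts)
            assert np.array_equal(clone.cells[key].m, cell.m)
        assert clone.max_global_activity == pytest.approx(model_a.max_global_activity)
        for d in range(7):
            assert clone.day_profiles[d].cs_list == model_a.day_profiles[d].cs_list
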