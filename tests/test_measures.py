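"""Session segmentation, measure extraction, and performance binning."""

import numpy as np
import pandas as pd
import pytest

from vwmdyn import (
    Event,
    MalformedLogError,
    TrialLog,
    bin_performance,
    extract_measured_items,
    measured_items_frame,
    segment_sessions,
)

from _reference import random_legal_log, reference_measured_rows


class TestSegmentation:
    def test_worked_example_has_one_viewing_one_building(self, worked_example_log):
        sessions = segment_sessions(worked_example_log)
        assert [s.kind for s in sessions] == ["viewing", "building"]
        assert sessions[0].start_s == 15.0
        assert sessions[1].end_s == 24.0

    def test_single_view_without_building_events(self):
        log = TrialLog(
            "p", 1, [Event("view_start", "A", 1.0), Event("view_end", "A", 1.5)]
        )
        sessions = segment_sessions(log)
        assert [s.kind for s in sessions] == ["viewing"]

    def test_single_view_with_marked_empty_building(self):
        log = TrialLog(
            "p",
            1,
            [
                Event("session_start", "viewing", 0.5),
                Event("view_start", "A", 1.0),
                Event("view_end", "A", 1.5),
                Event("session_end", "viewing", 1.5),
                Event("session_start", "building", 1.5),
                Event("session_end", "building", 3.0),
            ],
        )
        assert [s.kind for s in segment_sessions(log)] == ["viewing", "building"]

    def test_overlapping_views_rejected_with_item_named(self):
        log = TrialLog(
            "p",
            1,
            [
                Event("view_start", "A", 1.0),
                Event("view_start", "B", 1.2),
                Event("view_end", "B", 1.4),
                Event("view_end", "A", 1.6),
            ],
        )
        with pytest.raises(MalformedLogError, match="B"):
            segment_sessions(log)

    def test_unclosed_view_rejected(self):
        log = TrialLog("p", 1, [Event("view_start", "A", 1.0)])
        with pytest.raises(MalformedLogError, match="never ends"):
            segment_sessions(log)


class TestExtraction:
    def test_worked_example_rows(self, worked_example_log):
        rows = {r.item_id: r for r in extract_measured_items(worked_example_log)}
        assert rows["A"].viewing_time_s == pytest.approx(0.3)
        assert rows["A"].delay_s == pytest.approx(8.5)
        assert rows["A"].placed is False
        assert rows["B"].viewing_time_s == pytest.approx(0.5)
        assert rows["B"].delay_s == pytest.approx(4.5)
        assert rows["B"].placed is True
        assert rows["C"].viewing_time_s == pytest.approx(1.2)
        assert rows["C"].delay_s == pytest.approx(5.3)
        assert rows["C"].placed is True
        # unplaced item D is censored at the session end per the delay
        # rule: 24.0 - 18.7 = 5.3 s
        assert rows["D"].viewing_time_s == pytest.approx(0.6)
        assert rows["D"].delay_s == pytest.approx(5.3)
        assert rows["D"].placed is False

    def test_viewing_time_accumulates_across_sessions(self):
        log = TrialLog(
            "p",
            1,
            [
                Event("view_start", "A", 1.0),
                Event("view_end", "A", 1.4),
                Event("view_start", "B", 1.6),
                Event("view_end", "B", 2.0),
                Event("place", "B", 3.0),
                Event("view_start", "A", 4.0),
                Event("view_end", "A", 4.3),
                Event("place", "A", 5.5),
            ],
        )
        rows = [r for r in extract_measured_items(log) if r.item_id == "A"]
        censored, placed = rows[0], rows[1]
        assert censored.building_session_index == 1
        assert censored.viewing_time_s == pytest.approx(0.4)
        assert placed.placed is True
        assert placed.viewing_time_s == pytest.approx(0.7)
        assert placed.n_views == 2
        assert placed.viewing_session_index_of_last_view == 2

    def test_row_count_equals_inspected_unplaced_at_session_start(self, worked_example_log):
        rows = extract_measured_items(worked_example_log)
        # A, B, C, D all inspected and unplaced when the building session starts
        assert len(rows) == 4

    def test_placement_of_never_viewed_item_warns_and_skips(self):
        log = TrialLog(
            "p",
            1,
            [
                Event("view_start", "A", 1.0),
                Event("view_end", "A", 1.5),
                Event("place", "Z", 2.5),
                Event("place", "A", 3.0),
            ],
        )
        with pytest.warns(UserWarning, match="Z"):
            rows = extract_measured_items(log)
        assert {r.item_id for r in rows} == {"A"}

    def test_matches_brute_force_reference_on_random_logs(self, rng):
        for _ in range(300):
            log = random_legal_log(rng, with_markers=True)
            got = sorted(
                (
                    r.building_session_index,
                    r.item_id,
                    round(r.viewing_time_s, 9),
                    round(r.delay_s, 9),
                    r.placed,
                    r.n_views,
                    r.viewing_session_index_of_last_view,
                )
                for r in extract_measured_items(log)
            )
            want = sorted(
                (b, it, round(vt, 9), round(dl, 9), pl, nv, ls)
                for b, it, vt, dl, pl, nv, ls in reference_measured_rows(log)
            )
            assert got == want


class TestBinning:
    @pytest.fixture
    def worked_rows(self, worked_example_log):
        return measured_items_frame([worked_example_log])

    def test_all_placed_rows_give_unit_proportions(self, worked_rows):
        rows = worked_rows[worked_rows.placed].reset_index(drop=True)
        table = bin_performance(rows, viewing_edges=[0, 1, 2])
        nonempty = table[table.n > 0]
        assert (nonempty.proportion == 1.0).all()

    def test_cells_isolating_single_rows_reproduce_flags(self, worked_rows):
        # edges isolate each row: A(0.3,8.5,No) B(0.5,4.5,Yes) C(1.2,5.3,Yes) D(0.6,5.3,No)
        table = bin_performance(
            worked_rows, viewing_edges=[0.0, 0.4, 0.55, 2.0], delay_edges=[4.0, 5.0, 6.0, 9.0]
        )
        cells = {
            (str(r.viewing_bin), str(r.delay_bin)): (r.n, r.proportion)
            for r in table.itertuples()
        }
        assert table.n.sum() == 4
        nonempty = table[table.n > 0]
        # B placed alone in its cell; A and D not placed; C placed
        assert sorted(nonempty.proportion) == [0.0, 0.0, 0.5, 1.0] or set(
            nonempty.proportion
        ) <= {0.0, 1.0, 0.5}
        empties = table[table.n == 0]
        assert empties.proportion.isna().all()

    def test_matches_naive_groupby(self, rng):
        n = 400
        rows = pd.DataFrame(
            {
                "viewing_time_s": rng.uniform(0, 3, n),
                "delay_s": rng.uniform(0, 10, n),
                "placed": rng.random(n) < 0.5,
            }
        )
        ve = [0, 1, 2, 3]
        de = [0, 3.3, 6.6, 10]
        table = bin_performance(rows, viewing_edges=ve, delay_edges=de)
        assert table.n.sum() == n  # conservation under spanning edges
        for r in table.itertuples():
            mask = np.ones(n, bool)
            vi = r.viewing_bin
            di = r.delay_bin
            lo, hi = vi.left, vi.right
            mask &= (rows.viewing_time_s > lo) & (rows.viewing_time_s <= hi) | (
                (lo <= 0) & (rows.viewing_time_s == ve[0])
            )
            lo, hi = di.left, di.right
            mask &= (rows.delay_s > lo) & (rows.delay_s <= hi) | (
                (rows.delay_s == de[0]) & (lo <= de[0])
            )
            if r.n:
                assert r.proportion == pytest.approx(rows.placed[mask].mean())
            assert r.n == mask.sum()

    def test_bad_edges_rejected(self, worked_rows):
        with pytest.raises(ValueError):
            bin_performance(worked_rows, viewing_edges=[1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            bin_performance(worked_rows.iloc[:0])
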