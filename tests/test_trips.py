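"""Trip pairing rules, duration statistics, colony report and spreadsheet."""

from datetime import timedelta

import numpy as np
import pandas as pd
import pytest

from hivegate.segmentation import ENTER, EXIT, UNKNOWN, Event
from hivegate.trips import (
    build_report,
    extract_trips,
    trip_statistics,
    write_events_spreadsheet,
)

from conftest import make_det


def ev(category, t0, t1, tag_id=5059, x0=60.0, x1=650.0):
    """Two-detection event spanning [t0, t1] seconds with a set category."""
    dets = (make_det(t0, x=x0, tag_id=tag_id), make_det(t1, x=x1, tag_id=tag_id))
    return Event(tag_id=tag_id, detections=dets, category=category,
                 net_displacement=x0 - x1)


class TestExtractTrips:
    def test_exit_then_enter_pairs_with_measured_duration(self):
        trips = extract_trips([ev(EXIT, 0, 100), ev(ENTER, 183, 200)])
        assert len(trips) == 1
        assert trips[0].duration_seconds == pytest.approx(83.0)

    def test_enter_then_exit_is_no_trip(self):
        assert extract_trips([ev(ENTER, 0, 10), ev(EXIT, 100, 110)]) == []

    def test_latest_of_consecutive_exits_wins(self):
        e1 = ev(EXIT, 0, 10)
        e2 = ev(EXIT, 100, 110)
        trips = extract_trips([e1, e2, ev(ENTER, 300, 310)])
        assert len(trips) == 1
        assert trips[0].exit_event == e2  # e1 is a failed exit

    def test_unknowns_removed_before_pairing(self):
        trips = extract_trips(
            [ev(EXIT, 0, 10), ev(UNKNOWN, 100, 110), ev(ENTER, 300, 310)]
        )
        assert len(trips) == 1

    def test_empty_event_list(self):
        assert extract_trips([]) == []

    def test_unset_category_is_an_error(self):
        bare = Event(tag_id=1, detections=(make_det(0, tag_id=1),))
        with pytest.raises(ValueError, match="category"):
            extract_trips([bare])

    def test_ids_do_not_mix_and_each_event_used_once(self):
        events = (
            [ev(EXIT, 0, 10, tag_id=1001), ev(ENTER, 300, 310, tag_id=1001)]
            + [ev(EXIT, 5, 15, tag_id=2002), ev(ENTER, 400, 410, tag_id=2002),
               ev(ENTER, 600, 610, tag_id=2002)]
        )
        trips = extract_trips(events)
        assert [(t.tag_id,) for t in trips] == [(1001,), (2002,)]
        used = [t.exit_event for t in trips] + [t.enter_event for t in trips]
        assert len(used) == len(set(used))

    def test_adding_isolated_unknown_never_decreases_trip_count(self):
        base = [ev(EXIT, 0, 10), ev(ENTER, 300, 310), ev(EXIT, 600, 610),
                ev(ENTER, 900, 910)]
        n0 = len(extract_trips(base))
        for t_mid in (150, 450, 750, 1200):
            n1 = len(extract_trips(base + [ev(UNKNOWN, t_mid, t_mid + 5)]))
            assert n1 >= n0


class TestTripStatistics:
    def test_three_value_arithmetic(self):
        stats = trip_statistics([118.0, 118.0, 1118.0])
        assert stats.mode_seconds == 118
        assert stats.median_seconds == 118.0
        assert stats.mean_seconds == pytest.approx(451.33, abs=0.01)
        assert stats.n == sum(stats.histogram_counts) == 3

    def test_single_trip(self):
        stats = trip_statistics([83.0])
        assert stats.mean_seconds == stats.median_seconds == 83.0
        assert stats.mode_seconds == 83

    def test_mode_tie_breaks_to_smallest(self):
        stats = trip_statistics([70.0, 70.0, 90.0, 90.0, 300.0])
        assert stats.mode_seconds == 70

    def test_empty_is_flagged_not_nan(self):
        stats = trip_statistics([])
        assert stats.n == 0
        assert stats.mean_seconds is None
        assert stats.median_seconds is None
        assert stats.mode_seconds is None

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            trip_statistics([10.0, -1.0])

    def test_monte_carlo_mixture_mean_within_3_se(self):
        # mixture: 0.7 * Exponential(scale=120 s) + 0.3 * Uniform(600, 1200) s
        rng = np.random.default_rng(123)
        n = 10_000
        pick = rng.uniform(size=n) < 0.7
        durs = np.where(
            pick, rng.exponential(120.0, size=n), rng.uniform(600.0, 1200.0, size=n)
        )
        stats = trip_statistics(durs.tolist())
        true_mean = 0.7 * 120.0 + 0.3 * 900.0
        true_var = (
            0.7 * (120.0**2 + 120.0**2)
            + 0.3 * ((1200.0 - 600.0) ** 2 / 12 + 900.0**2)
            - true_mean**2
        )
        se = np.sqrt(true_var / n)
        assert abs(stats.mean_seconds - true_mean) < 3 * se


class TestReport:
    def _inputs(self):
        events = [
            ev(ENTER, 300, 310),
            ev(EXIT, 0, 10),
            ev(UNKNOWN, 500, 505),
            ev(UNKNOWN, 700, 705),
        ]
        detections = [d for e in events for d in e.detections]
        trips = extract_trips(events)
        return detections, events, trips

    def test_category_percentages(self):
        detections, events, trips = self._inputs()
        rep = build_report(detections, events, trips)
        assert rep.pct_enter == pytest.approx(25.0)
        assert rep.pct_exit == pytest.approx(25.0)
        assert rep.pct_unknown == pytest.approx(50.0)
        assert rep.pct_enter + rep.pct_exit + rep.pct_unknown == pytest.approx(100.0)
        assert rep.n_trips == 1
        assert rep.mean_detections_per_event == pytest.approx(2.0)

    def test_zero_detections_report(self):
        rep = build_report([], [], [])
        assert rep.n_detections == rep.n_events == rep.n_trips == 0
        assert rep.pct_enter is None
        assert "—" in rep.to_text()

    def test_inconsistent_inputs_name_the_relation(self):
        detections, events, trips = self._inputs()
        with pytest.raises(ValueError, match="partition"):
            build_report(detections[:-1], events, trips)
        foreign = extract_trips([ev(EXIT, 0, 10, tag_id=42),
                                 ev(ENTER, 300, 310, tag_id=42)])
        with pytest.raises(ValueError, match="event"):
            build_report(detections, events, foreign)

    def test_per_id_tallies(self):
        detections, events, trips = self._inputs()
        rep = build_report(detections, events, trips)
        row = rep.per_id.set_index("tag_id").loc[5059]
        assert row["detections"] == len(detections)
        assert row["events"] == 4
        assert row["trips"] == 1

    def test_cutoff_count(self):
        events = [ev(EXIT, 0, 10), ev(ENTER, 300, 310),
                  ev(EXIT, 1000, 1010), ev(ENTER, 9000, 9010)]
        detections = [d for e in events for d in e.detections]
        trips = extract_trips(events)
        rep = build_report(detections, events, trips, cutoff_hours=1.0)
        assert rep.n_trips == 2
        assert rep.n_trips_below_cutoff == 1  # 8000 s > 1 h


class TestSpreadsheet:
    def test_zero_events_header_only(self, tmp_path):
        csv_path, xlsx_path = write_events_spreadsheet([], tmp_path)
        df = pd.read_csv(csv_path)
        assert len(df) == 0
        assert list(df.columns) == [
            "tag_id", "t_start", "t_end", "n_detections", "category",
            "net_displacement",
        ]
        assert pd.read_excel(xlsx_path).empty

    def test_row_count_equals_event_count_and_round_trip(self, tmp_path):
        events = [ev(EXIT, i * 1000, i * 1000 + 10) for i in range(37)]
        csv_path, xlsx_path = write_events_spreadsheet(events, tmp_path)
        df = pd.read_csv(csv_path, parse_dates=["t_start", "t_end"])
        assert len(df) == 37
        assert (df["category"] == EXIT).all()
        assert list(df["t_start"]) == [e.t_start for e in events]
        assert len(pd.read_excel(xlsx_path)) == 37
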