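import datetime as dt

import pytest

import daniodb as d
from daniodb.core import DomainError, StatusColor, tank_status
from daniodb.facility import Position
from daniodb.reporting import (
    DailySummary,
    Period,
    ReportScope,
    export_chart_data,
    import_chart_data,
    water_quality_summarize,
)

from conftest import TODAY, make_tank

FACILITY = ReportScope("facility", "BCM-Main")
ROOM = ReportScope("room", "BCM-Main", room="T032")


def _place_seq(store, tanks, rack=1):
    for i, t in enumerate(tanks):
        d.place_tank(store, t.tuid, Position("T032", rack, "C", i + 1))


class TestFacilityStats:
    def test_empty_facility_all_zeros(self, store):
        stats = d.facility_stats(store, FACILITY)
        assert stats.total_tanks == stats.total_fish == 0
        assert all(n == 0 for n in stats.status_counts.values())

    def test_histogram_matches_per_tank_classification(self, store):
        ages = (5, 30, 100, 200, 400)
        tanks = [make_tank(store, age_days=a) for a in ages]
        _place_seq(store, tanks)
        stats = d.facility_stats(store, FACILITY)
        expected = {c: 0 for c in StatusColor}
        for t in tanks:
            expected[tank_status(t.dob, t.state, TODAY)] += 1
        assert stats.status_counts == expected
        assert stats.total_tanks == 5
        assert stats.total_fish == sum(t.fish_count for t in tanks)

    def test_facility_equals_sum_of_rooms(self, store):
        d.add_room(store, "BCM-Main", "T033")
        d.add_rack(store, "BCM-Main", "T033", d.RackLayout.custom([(10, 1)]))
        t1, t2, t3 = (make_tank(store, age_days=a) for a in (50, 100, 380))
        _place_seq(store, [t1, t2])
        d.place_tank(store, t3.tuid, Position("T033", 1, "A", 1))
        fac = d.facility_stats(store, FACILITY)
        rooms = [
            d.facility_stats(store, ReportScope("room", "BCM-Main", room=r))
            for r in ("T032", "T033")
        ]
        assert fac.total_tanks == sum(r.total_tanks for r in rooms)
        assert fac.total_fish == sum(r.total_fish for r in rooms)
        for color in StatusColor:
            assert fac.status_counts[color] == sum(
                r.status_counts[color] for r in rooms
            )

    def test_room_equals_sum_of_racks(self, store):
        tanks = [make_tank(store, age_days=a) for a in (50, 100)]
        _place_seq(store, tanks[:1], rack=1)
        d.place_tank(store, tanks[1].tuid, Position("T032", 2, "A", 1))
        room = d.facility_stats(store, ROOM)
        racks = [
            d.facility_stats(
                store, ReportScope("rack", "BCM-Main", room="T032", rack_index=i)
            )
            for i in (1, 2, 3)
        ]
        assert room.total_tanks == sum(r.total_tanks for r in racks) == 2


class TestPeriods:
    def test_week_is_seven_daily_buckets(self):
        period = Period("week", TODAY)
        buckets = period.buckets()
        assert len(buckets) == 7
        assert buckets[0][0] == TODAY - dt.timedelta(days=6)
        assert buckets[-1] == (TODAY, TODAY)

    def test_year_is_twelve_month_buckets(self):
        buckets = Period("year", TODAY).buckets()
        assert len(buckets) == 12
        assert buckets[0][0] == dt.date(2025, 7, 1)
        assert buckets[-1] == (dt.date(2026, 6, 1), dt.date(2026, 6, 30))

    def test_month_buckets_partition_the_month(self):
        buckets = Period("month", TODAY).buckets()
        days = []
        for start, end in buckets:
            day = start
            while day <= end:
                days.append(day)
                day += dt.timedelta(days=1)
        assert days == [dt.date(2026, 6, day) for day in range(1, 31)]

    def test_unknown_kind_rejected(self):
        with pytest.raises(DomainError):
            Period("quarter", TODAY)


class TestVitality:
    def _cross(self, store):
        sire, dam = make_tank(store), make_tank(store)
        _place_seq(store, [sire, dam])
        return d.set_up_cross(store, sire.tuid, dam.tuid, "pair")

    def test_raise_fry_counts_as_births_this_week(self, store):
        cross = self._cross(store)
        d.raise_fry(store, cross.cuid, fry_per_dish=30, n_dishes=2, dob=TODAY)
        buckets = d.vitality_summary(store, FACILITY, Period("week", TODAY))
        assert buckets[-1].births == 60
        assert sum(b.births for b in buckets) == 60

    def test_mortality_kinds_split_into_columns(self, store):
        tank = make_tank(store, males=5, females=5)
        _place_seq(store, [tank])
        d.report_dead(store, tank.tuid, 2, "found_dead", "unknown", date=TODAY)
        d.report_dead(store, tank.tuid, 3, "euthanized", "old age", date=TODAY)
        bucket = d.vitality_summary(store, FACILITY, Period("week", TODAY))[-1]
        assert (bucket.births, bucket.found_dead, bucket.euthanized) == (0, 2, 3)

    def test_empty_period_has_dense_zero_buckets(self, store):
        buckets = d.vitality_summary(store, FACILITY, Period("year", TODAY))
        assert len(buckets) == 12
        assert all((b.births, b.found_dead, b.euthanized) == (0, 0, 0) for b in buckets)


class TestMortalitySummary:
    def test_cause_distribution_normalizes(self, store):
        tank = make_tank(store, males=5, females=5)
        _place_seq(store, [tank])
        d.report_dead(store, tank.tuid, 2, "found_dead", "fungus", symptom="lesions")
        d.report_dead(store, tank.tuid, 2, "found_dead", "age", symptom="lethargy")
        summary = d.mortality_summary(store, FACILITY, Period("week", TODAY))
        assert summary.causes == {"age": 0.5, "fungus": 0.5}
        assert sum(summary.causes.values()) == pytest.approx(1.0, abs=1e-9)
        assert summary.symptoms_found_dead == {"lesions": 0.5, "lethargy": 0.5}

    def test_no_reports_no_division_by_zero(self, store):
        summary = d.mortality_summary(store, FACILITY, Period("week", TODAY))
        assert summary.causes == {}
        assert summary.total_dead == 0

    def test_dead_totals_agree_with_vitality(self, store):
        tank = make_tank(store, males=6, females=6)
        _place_seq(store, [tank])
        d.report_dead(store, tank.tuid, 2, "found_dead", "unknown", date=TODAY)
        d.report_dead(store, tank.tuid, 1, "euthanized", "old age", date=TODAY)
        period = Period("week", TODAY)
        vit = d.vitality_summary(store, FACILITY, period)
        mort = d.mortality_summary(store, FACILITY, period)
        assert mort.total_dead == sum(b.found_dead + b.euthanized for b in vit)
        assert sum(n for _, n in mort.buckets) == mort.total_dead


class TestDeadFishReport:
    def test_range_filter_and_sorting(self, store):
        tank = make_tank(store, males=6, females=6)
        _place_seq(store, [tank])
        for offset in (10, 5, 1, 40):
            d.report_dead(
                store, tank.tuid, 1, "found_dead", "unknown",
                date=TODAY - dt.timedelta(days=offset),
            )
        rows = d.dead_fish_report(
            store, "BCM-Main", TODAY - dt.timedelta(days=30), TODAY
        )
        assert len(rows) == 3
        assert [r["date"] for r in rows] == sorted(r["date"] for r in rows)

    def test_inverted_range_rejected(self, store):
        with pytest.raises(DomainError):
            d.dead_fish_report(store, "BCM-Main", TODAY, TODAY - dt.timedelta(1))

    def test_rows_respect_lab_visibility(self, store):
        mine = make_tank(store, user="alice", males=4, females=4)
        theirs = make_tank(store, user="bob", allele="alleleB", males=4, females=4)
        _place_seq(store, [mine, theirs])
        d.report_dead(store, mine.tuid, 1, "found_dead", "unknown", date=TODAY)
        d.report_dead(store, theirs.tuid, 1, "found_dead", "unknown", date=TODAY)
        all_rows = d.dead_fish_report(store, "BCM-Main", TODAY, TODAY)
        alice_rows = d.dead_fish_report(store, "BCM-Main", TODAY, TODAY, as_user="alice")
        assert len(all_rows) == 2
        assert [r["tuid"] for r in alice_rows] == [mine.tuid]


class TestLabUsage:
    def test_counts_active_records_only(self, store):
        tanks = [make_tank(store, user="alice") for _ in range(5)]
        d.retire_tank(store, tanks[-1].tuid)
        cross = d.set_up_cross(store, tanks[0].tuid, tanks[1].tuid, "pair")
        d.raise_fry(store, cross.cuid, 20)
        usage = d.lab_usage_report(store, "Wythe")
        assert usage == {"active_tanks": 4, "active_crosses": 1, "nursery_tanks": 1}

    def test_empty_lab_is_zero(self, store):
        assert d.lab_usage_report(store, "Martin") == {
            "active_tanks": 0, "active_crosses": 0, "nursery_tanks": 0,
        }

    def test_unknown_lab_rejected(self, store):
        with pytest.raises(DomainError):
            d.lab_usage_report(store, "Nobody")

    def test_lab_partition_sums_to_facility_totals(self, store):
        for user, allele in (("alice", "alleleA"), ("bob", "alleleB")):
            for _ in range(2):
                make_tank(store, user=user, allele=allele)
        total = sum(
            d.lab_usage_report(store, lab)["active_tanks"] for lab in ("Wythe", "Martin")
        )
        assert total == len(store.tanks)


class TestWaterQuality:
    def test_daily_mean_and_n(self, store):
        rec = d.ingest_water_quality(
            store, "BCM-Main", "T032", 1, 2026, 5, "pH",
            [(3, 7.2), (3, 7.4), (10, 7.0)],
        )
        summaries = water_quality_summarize(rec)
        day3 = summaries[0]
        assert (day3.day, day3.n) == (3, 2)
        assert day3.mean == pytest.approx(7.3)
        assert day3.sd == pytest.approx(0.1414213562, rel=1e-6)

    def test_single_reading_day_sd_zero(self, store):
        rec = d.ingest_water_quality(
            store, "BCM-Main", "T032", 1, 2026, 5, "conductivity", [(1, 700.0)]
        )
        assert water_quality_summarize(rec) == [DailySummary(1, 700.0, 0.0, 1)]

    def test_day_31_in_april_rejected_at_ingest(self, store):
        with pytest.raises(DomainError, match="day 31"):
            d.ingest_water_quality(
                store, "BCM-Main", "T032", 1, 2026, 4, "pH", [(31, 7.0)]
            )

    def test_unknown_parameter_rejected(self, store):
        with pytest.raises(DomainError, match="parameter"):
            d.ingest_water_quality(
                store, "BCM-Main", "T032", 1, 2026, 5, "salinity", [(1, 1.0)]
            )

    def test_summary_invariant_under_reading_permutation(self, store):
        readings = [(1, 7.1), (2, 7.3), (1, 7.5), (2, 7.2), (1, 7.0)]
        rec1 = d.ingest_water_quality(
            store, "BCM-Main", "T032", 1, 2026, 5, "pH", readings
        )
        rec2 = d.ingest_water_quality(
            store, "BCM-Main", "T032", 1, 2026, 5, "pH", list(reversed(readings))
        )
        assert water_quality_summarize(rec1) == water_quality_summarize(rec2)


class TestChartExport:
    def test_vitality_round_trips_through_csv_and_json(self, store):
        tank = make_tank(store, males=5, females=5)
        _place_seq(store, [tank])
        d.report_dead(store, tank.tuid, 2, "found_dead", "unknown", date=TODAY)
        buckets = d.vitality_summary(store, FACILITY, Period("week", TODAY))
        for fmt in ("csv", "json"):
            frame = import_chart_data(export_chart_data(buckets, fmt), fmt)
            assert list(frame.columns) == ["label", "births", "found_dead", "euthanized"]
            assert frame["found_dead"].sum() == 2

    def test_water_quality_export_carries_day_mean_sd(self, store):
        rec = d.ingest_water_quality(
            store, "BCM-Main", "T032", 1, 2026, 5, "pH", [(3, 7.2), (3, 7.4)]
        )
        frame = import_chart_data(
            export_chart_data(water_quality_summarize(rec), "json"), "json"
        )
        assert list(frame.columns) == ["label", "value", "error"]
        assert frame.loc[0, "value"] == pytest.approx(7.3)

    def test_empty_report_is_header_only(self):
        text = export_chart_data([], "csv")
        assert text.strip() == "label,value"

    def test_unsupported_format_rejected(self):
        with pytest.raises(DomainError):
            export_chart_data([], "xlsx")
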