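"""Census, vitality, mortality, usage, and water-quality reporting.

Reports aggregate at three nested scopes — facility, room, or rack — and
over three reporting windows:

* ``week``  — the seven days ending at the anchor date, daily buckets;
* ``month`` — the anchor's calendar month, Monday-start week buckets;
* ``year``  — the twelve calendar months ending with the anchor's month,
  monthly buckets.

Buckets are dense: a bucket with no activity is reported with zero counts
rather than omitted, so chart series always align. Scope membership of
births and deaths uses the rack location snapshotted onto each nursery or
mortality record when it was created, which keeps historical reports
stable when tanks later move or retire.
"""

from __future__ import annotations

import calendar
import datetime as dt
import io as _io
import json
import statistics
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import pandas as pd

from .core import DomainError, StatusColor, tank_status
from .lifecycle import MortalityKind, MortalityReport

if TYPE_CHECKING:  # pragma: no cover
    from .store import ColonyStore

__all__ = [
    "ReportScope",
    "Period",
    "ReportBucket",
    "FacilityStats",
    "MortalitySummary",
    "WATER_PARAMETERS",
    "WaterQualityRecord",
    "DailySummary",
    "facility_stats",
    "vitality_summary",
    "mortality_summary",
    "dead_fish_report",
    "lab_usage_report",
    "ingest_water_quality",
    "water_quality_summarize",
    "export_chart_data",
    "import_chart_data",
]

WATER_PARAMETERS = (
    "conductivity",
    "pH",
    "temperature",
    "nitrites",
    "nitrates",
    "chlorine",
)


@dataclass(frozen=True)
class ReportScope:
    """facility ⊃ room ⊃ rack; narrower levels pin more coordinates."""

    level: str  # facility | room | rack
    facility: str
    room: Optional[str] = None
    rack_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.level not in ("facility", "room", "rack"):
            raise DomainError(f"unknown scope level {self.level!r}")
        if self.level in ("room", "rack") and self.room is None:
            raise DomainError(f"{self.level} scope needs a room")
        if self.level == "rack" and self.rack_index is None:
            raise DomainError("rack scope needs a rack index")

    def contains(
        self, facility: Optional[str], room: Optional[str], rack_index: Optional[int]
    ) -> bool:
        if facility != self.facility:
            return False
        if self.level == "facility":
            return True
        if room != self.room:
            return False
        if self.level == "room":
            return True
        return rack_index == self.rack_index


@dataclass(frozen=True)
class Period:
    kind: str  # week | month | year
    anchor: dt.date

    def __post_init__(self) -> None:
        if self.kind not in ("week", "month", "year"):
            raise DomainError(f"unknown period kind {self.kind!r}")

    def window(self) -> tuple[dt.date, dt.date]:
        """Inclusive (start, end) of the reporting window."""
        a = self.anchor
        if self.kind == "week":
            return a - dt.timedelta(days=6), a
        if self.kind == "month":
            last = calendar.monthrange(a.year, a.month)[1]
            return a.replace(day=1), a.replace(day=last)
        start_month = (a.year * 12 + a.month - 1) - 11
        start = dt.date(start_month // 12, start_month % 12 + 1, 1)
        last = calendar.monthrange(a.year, a.month)[1]
        return start, a.replace(day=last)

    def buckets(self) -> list[tuple[dt.date, dt.date]]:
        """Dense (start, end) sub-buckets partitioning the window."""
        start, end = self.window()
        if self.kind == "week":
            return [
                (start + dt.timedelta(days=i),) * 2 for i in range(7)
            ]
        if self.kind == "month":
            out = []
            # Monday-start weeks clipped to the calendar month
            cursor = start - dt.timedelta(days=start.weekday())
            while cursor <= end:
                b_start = max(cursor, start)
                b_end = min(cursor + dt.timedelta(days=6), end)
                out.append((b_start, b_end))
                cursor += dt.timedelta(days=7)
            return out
        out = []
        cursor = start
        while cursor <= end:
            last = calendar.monthrange(cursor.year, cursor.month)[1]
            out.append((cursor, cursor.replace(day=last)))
            cursor = (cursor.replace(day=last) + dt.timedelta(days=1))
        return out


@dataclass
class ReportBucket:
    start: dt.date
    end: dt.date
    births: int = 0
    found_dead: int = 0
    euthanized: int = 0


@dataclass
class FacilityStats:
    scope: ReportScope
    status_counts: dict[StatusColor, int]
    total_tanks: int
    total_fish: int


@dataclass
class MortalitySummary:
    """Cause/symptom breakdowns (fractions of dead fish) plus dead counts."""

    causes: dict[str, float]
    symptoms_euthanized: dict[str, float]
    symptoms_found_dead: dict[str, float]
    buckets: list[tuple[dt.date, int]]
    total_dead: int


@dataclass
class WaterQualityRecord:
    facility: str
    room: str
    rack_index: int
    year: int
    month: int
    parameter: str
    readings: list[tuple[int, float]] = field(default_factory=list)


@dataclass(frozen=True)
class DailySummary:
    day: int
    mean: float
    sd: float
    n: int


# ---------------------------------------------------------------------------
# Census and vitality
# ---------------------------------------------------------------------------


def _scoped_tanks(store: "ColonyStore", scope: ReportScope):
    for tank in store.tanks.values():
        loc = tank.location
        if loc is None:
            continue
        if scope.contains(tank.facility_name, loc.room, loc.rack_index):
            yield tank


def facility_stats(store: "ColonyStore", scope: ReportScope) -> FacilityStats:
    """Status-colour histogram plus tank and fish totals for a scope.

    Counts tanks placed on racks within the scope; retired tanks have
    been removed from their racks and so drop out of the census.
    """
    today = store.clock.today()
    counts = {c: 0 for c in StatusColor}
    tanks = fish = 0
    for tank in _scoped_tanks(store, scope):
        counts[tank_status(tank.dob, tank.state, today)] += 1
        tanks += 1
        fish += tank.fish_count
    return FacilityStats(scope, counts, tanks, fish)


def _in_bucket(day: dt.date, bucket: tuple[dt.date, dt.date]) -> bool:
    return bucket[0] <= day <= bucket[1]


def _scoped_mortality(
    store: "ColonyStore", scope: ReportScope
) -> list[MortalityReport]:
    return [
        r
        for r in store.mortality_reports
        if scope.contains(r.facility_name, r.room, r.rack_index)
    ]


def vitality_summary(
    store: "ColonyStore", scope: ReportScope, period: Period
) -> list[ReportBucket]:
    """Fish born (nursery fry), found dead, and euthanized per bucket."""
    buckets = [ReportBucket(s, e) for s, e in period.buckets()]
    for rec in store.nursery.values():
        if not scope.contains(rec.facility_name, rec.room, rec.rack_index):
            continue
        for b in buckets:
            if _in_bucket(rec.dob, (b.start, b.end)):
                b.births += rec.initial_fry
                break
    for rep in _scoped_mortality(store, scope):
        for b in buckets:
            if _in_bucket(rep.date, (b.start, b.end)):
                if rep.kind is MortalityKind.FOUND_DEAD:
                    b.found_dead += rep.n_dead
                else:
                    b.euthanized += rep.n_dead
                break
    return buckets


def _distribution(pairs: list[tuple[str, int]]) -> dict[str, float]:
    total = sum(n for _, n in pairs)
    if total == 0:
        return {}
    out: dict[str, int] = {}
    for key, n in pairs:
        out[key] = out.get(key, 0) + n
    return {k: v / total for k, v in sorted(out.items())}


def mortality_summary(
    store: "ColonyStore", scope: ReportScope, period: Period
) -> MortalitySummary:
    """Cause and symptom breakdowns of dead fish, plus bucketed counts.

    Fractions are weighted by the number of dead fish in each report and
    each nonempty distribution sums to one.
    """
    start, end = period.window()
    reports = [
        r for r in _scoped_mortality(store, scope) if start <= r.date <= end
    ]
    causes = _distribution([(r.cause, r.n_dead) for r in reports])
    sym_eu = _distribution(
        [(r.symptom, r.n_dead) for r in reports if r.kind is MortalityKind.EUTHANIZED]
    )
    sym_fd = _distribution(
        [(r.symptom, r.n_dead) for r in reports if r.kind is MortalityKind.FOUND_DEAD]
    )
    buckets = []
    for b_start, b_end in period.buckets():
        n = sum(
            r.n_dead for r in reports if _in_bucket(r.date, (b_start, b_end))
        )
        buckets.append((b_start, n))
    return MortalitySummary(
        causes=causes,
        symptoms_euthanized=sym_eu,
        symptoms_found_dead=sym_fd,
        buckets=buckets,
        total_dead=sum(r.n_dead for r in reports),
    )


def dead_fish_report(
    store: "ColonyStore",
    facility: str,
    date_from: dt.date,
    date_to: dt.date,
    as_user: Optional[str] = None,
) -> list[dict]:
    """Printable dead-fish rows for a facility and date range.

    When *as_user* is given, rows are restricted to tanks the user's lab
    may view.
    """
    if date_from > date_to:
        raise DomainError(f"inverted date range {date_from} > {date_to}")
    from .access import Action, can  # local import avoids a cycle

    rows = []
    for rep in store.mortality_reports:
        if rep.facility_name != facility or not date_from <= rep.date <= date_to:
            continue
        if as_user is not None and not can(
            store, as_user, Action.VIEW, "mortality_report", rep
        ):
            continue
        tank = store.tanks.get(rep.tank)
        rows.append(
            {
                "date": rep.date,
                "tuid": rep.tank,
                "line": tank.line if tank else "",
                "lab": store.users[tank.user].lab if tank else "",
                "n_dead": rep.n_dead,
                "kind": rep.kind.value,
                "cause": rep.cause,
                "symptom": rep.symptom,
            }
        )
    rows.sort(key=lambda r: (r["date"], r["tuid"]))
    return rows


def lab_usage_report(store: "ColonyStore", lab: str) -> dict[str, int]:
    """Active tank/cross and nursery counts for one lab (billing, IACUC)."""
    if lab not in store.labs:
        raise DomainError(f"unknown lab {lab!r}")
    members = {u.name for u in store.users.values() if u.lab == lab}
    active_tanks = sum(
        1
        for t in store.tanks.values()
        if t.user in members and t.state.value == "active"
    )
    active_crosses = sum(
        1
        for c in store.crosses.values()
        if c.user in members and not c.retired
    )
    lab_cuids = {c.cuid for c in store.crosses.values() if c.user in members}
    on_nursery = sum(
        1
        for n in store.nursery.values()
        if n.cuid in lab_cuids and n.state == "on_nursery"
    )
    return {
        "active_tanks": active_tanks,
        "active_crosses": active_crosses,
        "nursery_tanks": on_nursery,
    }


# ---------------------------------------------------------------------------
# Water quality
# ---------------------------------------------------------------------------


def ingest_water_quality(
    store: "ColonyStore",
    facility: str,
    room: str,
    rack_index: int,
    year: int,
    month: int,
    parameter: str,
    readings: Sequence[tuple[int, float]],
) -> WaterQualityRecord:
    """Store (day, value) water readings for one rack-month.

    Readings are validated against the calendar at ingest so downstream
    summaries never see an impossible day.
    """
    if parameter not in WATER_PARAMETERS:
        raise DomainError(
            f"unknown water parameter {parameter!r}; expected one of {WATER_PARAMETERS}"
        )
    store.room(facility, room)  # referential check
    n_days = calendar.monthrange(year, month)[1]
    for day, _ in readings:
        if not 1 <= day <= n_days:
            raise DomainError(
                f"day {day} outside {year}-{month:02d} (has {n_days} days)"
            )
    record = WaterQualityRecord(
        facility=facility,
        room=room,
        rack_index=rack_index,
        year=year,
        month=month,
        parameter=parameter,
        readings=[(int(d), float(v)) for d, v in readings],
    )
    store.water_quality.append(record)
    return record


def water_quality_summarize(record: WaterQualityRecord) -> list[DailySummary]:
    """Per-day mean and sample SD (error bars); one summary per day read."""
    by_day: dict[int, list[float]] = {}
    for day, value in record.readings:
        by_day.setdefault(day, []).append(value)
    out = []
    for day in sorted(by_day):
        values = by_day[day]
        sd = statistics.stdev(values) if len(values) > 1 else 0.0
        out.append(
            DailySummary(day=day, mean=statistics.fmean(values), sd=sd, n=len(values))
        )
    return out


# ---------------------------------------------------------------------------
# Chart-data export
# ---------------------------------------------------------------------------


def _to_frame(report) -> pd.DataFrame:
    if isinstance(report, list) and report and isinstance(report[0], ReportBucket):
        return pd.DataFrame(
            {
                "label": [b.start.isoformat() for b in report],
                "births": [b.births for b in report],
                "found_dead": [b.found_dead for b in report],
                "euthanized": [b.euthanized for b in report],
            }
        )
    if isinstance(report, list) and report and isinstance(report[0], DailySummary):
        return pd.DataFrame(
            {
                "label": [s.day for s in report],
                "value": [s.mean for s in report],
                "error": [s.sd for s in report],
            }
        )
    if isinstance(report, dict):
        return pd.DataFrame(
            {"label": list(report.keys()), "value": list(report.values())}
        )
    if isinstance(report, FacilityStats):
        return pd.DataFrame(
            {
                "label": [c.value for c in report.status_counts],
                "value": list(report.status_counts.values()),
            }
        )
    if isinstance(report, list) and not report:
        return pd.DataFrame({"label": [], "value": []})
    raise DomainError(f"cannot export report of type {type(report).__name__}")


def export_chart_data(report, format: str = "csv") -> str:
    """Serialize a report to a chart-ready table (columns label, value...).

    The serialization is lossless: :func:`import_chart_data` reproduces
    the exported values exactly.
    """
    frame = _to_frame(report)
    if format == "csv":
        return frame.to_csv(index=False)
    if format == "json":
        return json.dumps(frame.to_dict(orient="records"))
    raise DomainError(f"unsupported chart format {format!r}")


def import_chart_data(text: str, format: str = "csv") -> pd.DataFrame:
    """Read a table written by :func:`export_chart_data`."""
    if format == "csv":
        return pd.read_csv(_io.StringIO(text))
    if format == "json":
        return pd.DataFrame(json.loads(text))
    raise DomainError(f"unsupported chart format {format!r}")
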