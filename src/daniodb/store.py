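"""The in-memory colony store: registries plus every record collection.

A :class:`ColonyStore` is the single-writer container the operation
modules act on. Persistence to a single-file relational database lives in
:mod:`daniodb.io`; the store itself is plain objects so tests and library
callers can build colonies without touching disk.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

from .core import Clock, DomainError, SerialRegistry
from .access import Lab, User
from .facility import Facility, Room
from .lifecycle import (
    CalendarEvent,
    Cross,
    FollowUpReport,
    GenotypingProtocol,
    Harvest,
    Line,
    MortalityReport,
    NurseryRecord,
    Tank,
)
from .reporting import WaterQualityRecord

__all__ = ["ColonyStore", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

logger = logging.getLogger("daniodb")


def _log_sink(event: CalendarEvent, recipients: list[str]) -> None:
    logger.info(
        "reminder due %s: %s -> %s", event.date, event.title, ", ".join(recipients)
    )


@dataclass
class ColonyStore:
    clock: Clock = field(default_factory=Clock.system)
    registry: SerialRegistry = field(default_factory=SerialRegistry)
    schema_version: int = SCHEMA_VERSION
    seed: Optional[int] = None

    labs: dict[str, Lab] = field(default_factory=dict)
    users: dict[str, User] = field(default_factory=dict)
    facilities: dict[str, Facility] = field(default_factory=dict)
    lines: dict[str, Line] = field(default_factory=dict)
    protocols: dict[str, GenotypingProtocol] = field(default_factory=dict)
    tanks: dict[str, Tank] = field(default_factory=dict)
    crosses: dict[str, Cross] = field(default_factory=dict)
    nursery: dict[str, NurseryRecord] = field(default_factory=dict)
    harvests: dict[str, Harvest] = field(default_factory=dict)
    mortality_reports: list[MortalityReport] = field(default_factory=list)
    follow_ups: list[FollowUpReport] = field(default_factory=list)
    events: list[CalendarEvent] = field(default_factory=list)
    water_quality: list[WaterQualityRecord] = field(default_factory=list)

    #: pluggable notification delivery (default: log); takes (event, recipients)
    notification_sink: Callable[[CalendarEvent, list[str]], None] = _log_sink

    # -- lookups -----------------------------------------------------------

    def lab(self, name: str) -> Lab:
        try:
            return self.labs[name]
        except KeyError:
            raise DomainError(f"unknown lab {name!r}") from None

    def user(self, name: str) -> User:
        try:
            return self.users[name]
        except KeyError:
            raise DomainError(f"unknown user {name!r}") from None

    def facility(self, name: str) -> Facility:
        try:
            return self.facilities[name]
        except KeyError:
            raise DomainError(f"unknown facility {name!r}") from None

    def default_facility_name(self) -> str:
        if not self.facilities:
            raise DomainError("no facility configured")
        return next(iter(self.facilities))

    def room(self, facility: str, name: str) -> Room:
        fac = self.facility(facility)
        try:
            return fac.rooms[name]
        except KeyError:
            raise DomainError(
                f"unknown room {name!r} in facility {facility!r}"
            ) from None

    def line_by_allele(self, allele_name: str) -> Line:
        for line in self.lines.values():
            if line.allele_name == allele_name:
                return line
        raise DomainError(f"unknown allele {allele_name!r}")

    def allele_vocabulary(self) -> set[str]:
        """The controlled allele vocabulary: one entry per registered line."""
        return {line.allele_name for line in self.lines.values()}

    def tank(self, tuid: str) -> Tank:
        try:
            return self.tanks[tuid]
        except KeyError:
            raise DomainError(f"unknown tank {tuid!r}") from None

    def cross(self, cuid: str) -> Cross:
        try:
            return self.crosses[cuid]
        except KeyError:
            raise DomainError(f"unknown cross {cuid!r}") from None

    def nursery_record(self, nuid: str) -> NurseryRecord:
        try:
            return self.nursery[nuid]
        except KeyError:
            raise DomainError(f"unknown nursery record {nuid!r}") from None

    def harvest(self, huid: str) -> Harvest:
        try:
            return self.harvests[huid]
        except KeyError:
            raise DomainError(f"unknown harvest {huid!r}") from None

    def max_issued_serial(self, prefix: str) -> int:
        """Highest serial of *prefix* still present in the store."""
        from .core import Identifier

        collections: dict[str, list[str]] = {
            "T": list(self.tanks),
            "C": list(self.crosses),
            "N": list(self.nursery),
            "H": list(self.harvests),
            "L": list(self.lines),
        }
        serials = [Identifier.parse(r).serial for r in collections.get(prefix, [])]
        return max(serials, default=0)

    def set_today(self, day: dt.date) -> None:
        """Pin the store's clock to a fixed date (used by the CLI --date)."""
        self.clock = Clock.fixed(day)
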