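"""Core domain primitives for a zebrafish colony database.

Every husbandry record in the store is keyed by a prefixed serial
identifier (T = tank, C = cross, N = nursery, H = harvest, L = line),
issued by a per-prefix registry and rendered zero-padded to four digits
("T0370"). Harvest resources carry an extra sub-index ("H0001-1").

The age/status classifiers in this module are pure functions of dates so
that every caller (rack views, census reports, labels) colours a tank the
same way:

* white  — younger than 2 weeks (< 14 days)
* yellow — 2 weeks to 3 months  (14–89 days)
* green  — 3 months to 1 year   (90–364 days), mating age
* red    — 1 year or older      (>= 365 days), due for turnover
* black  — retired or euthanized, regardless of age

All date arithmetic goes through an injectable :class:`Clock`; nothing in
the package reads the wall clock directly, which keeps behaviour
reproducible in tests and lets the CLI pin "today" with ``--date``.
"""

from __future__ import annotations

import datetime as dt
import enum
import re
from dataclasses import dataclass, field
from typing import Callable, Optional

__all__ = [
    "PREFIXES",
    "Identifier",
    "SerialRegistry",
    "StatusColor",
    "CrossColor",
    "SexComposition",
    "LifecycleState",
    "Clock",
    "DomainError",
    "next_uid",
    "reset_serial",
    "tank_status",
    "cross_color",
    "sex_display",
    "turnover_date",
]

#: Valid identifier prefixes: Tank, Cross, Nursery, Harvest, Line.
PREFIXES = ("T", "C", "N", "H", "L")

#: Age-class thresholds in days (lower bound inclusive for the later class).
AGE_YELLOW_DAYS = 14
AGE_GREEN_DAYS = 90
AGE_RED_DAYS = 365

#: Fry graduate from the nursery to the main system at this age.
GRADUATION_AGE_DAYS = 5

#: Number of backup snapshots retained by the rotation policy.
BACKUP_RETENTION = 7


class DomainError(ValueError):
    """Raised when an operation violates a colony-model precondition."""


_ID_RE = re.compile(r"^([TCNHL])(\d{4,})(?:-(\d+))?$")


@dataclass(frozen=True, order=True)
class Identifier:
    """A prefixed serial identifier such as ``T0370`` or ``H0001-2``.

    ``sub_index`` is only meaningful for harvest resources, where the
    harvest's embryos or adults are split into sub-indexed groups.
    """

    prefix: str
    serial: int
    sub_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.prefix not in PREFIXES:
            raise DomainError(f"unknown identifier prefix {self.prefix!r}")
        if self.serial < 1:
            raise DomainError("identifier serial must be positive")
        if self.sub_index is not None and self.sub_index < 1:
            raise DomainError("identifier sub-index must be positive")

    @property
    def rendered(self) -> str:
        base = f"{self.prefix}{self.serial:04d}"
        if self.sub_index is not None:
            return f"{base}-{self.sub_index}"
        return base

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.rendered

    @classmethod
    def parse(cls, text: str) -> "Identifier":
        """Parse a rendered identifier back to (prefix, serial, sub_index)."""
        m = _ID_RE.match(text.strip())
        if not m:
            raise DomainError(f"not a valid identifier: {text!r}")
        prefix, serial, sub = m.groups()
        return cls(prefix, int(serial), int(sub) if sub is not None else None)


@dataclass
class SerialRegistry:
    """Per-prefix counters issuing strictly increasing serials."""

    next_serial: dict[str, int] = field(
        default_factory=lambda: {p: 1 for p in PREFIXES}
    )

    def copy(self) -> "SerialRegistry":
        return SerialRegistry(dict(self.next_serial))


def next_uid(registry: SerialRegistry, prefix: str) -> Identifier:
    """Issue the next identifier for *prefix* and advance the registry."""
    if prefix not in PREFIXES:
        raise DomainError(f"unknown identifier prefix {prefix!r}")
    serial = registry.next_serial[prefix]
    registry.next_serial[prefix] = serial + 1
    return Identifier(prefix, serial)


def reset_serial(
    registry: SerialRegistry,
    prefix: str,
    new_next: int,
    max_issued_in_store: int = 0,
) -> SerialRegistry:
    """Reset the next serial for *prefix* (e.g. after deleting a record).

    Refuses any value that would collide with a serial still present in
    the store: ``new_next`` must exceed ``max_issued_in_store``.
    """
    if prefix not in PREFIXES:
        raise DomainError(f"unknown identifier prefix {prefix!r}")
    if new_next < 1:
        raise DomainError("next serial must be positive")
    if new_next <= max_issued_in_store:
        raise DomainError(
            f"next serial {new_next} would duplicate an existing "
            f"{prefix} identifier (max issued is {max_issued_in_store})"
        )
    registry.next_serial[prefix] = new_next
    return registry


class StatusColor(str, enum.Enum):
    """Tank age/lifecycle colour code."""

    WHITE = "white"
    YELLOW = "yellow"
    GREEN = "green"
    RED = "red"
    BLACK = "black"


class CrossColor(str, enum.Enum):
    """Cross freshness colour code."""

    GREEN = "green"
    RED = "red"
    GRAY = "gray"


class LifecycleState(str, enum.Enum):
    ACTIVE = "active"
    RETIRED = "retired"
    EUTHANIZED = "euthanized"


#: Terminal lifecycle states; no transition leaves them.
TERMINAL_STATES = frozenset({LifecycleState.RETIRED, LifecycleState.EUTHANIZED})


@dataclass(frozen=True)
class SexComposition:
    """Counts of sexed and unsexed fish in a tank."""

    males: int = 0
    females: int = 0
    unsexed: int = 0

    def __post_init__(self) -> None:
        if min(self.males, self.females, self.unsexed) < 0:
            raise DomainError("sex counts must be non-negative")

    @property
    def total(self) -> int:
        return self.males + self.females + self.unsexed


@dataclass(frozen=True)
class Clock:
    """Injectable calendar-date provider.

    ``Clock.fixed(d)`` freezes today at *d*; ``Clock.system()`` tracks the
    real calendar. Operations take dates from the store's clock, never
    from ``date.today()`` directly.
    """

    _provider: Callable[[], dt.date]

    def today(self) -> dt.date:
        return self._provider()

    @classmethod
    def fixed(cls, day: dt.date) -> "Clock":
        return cls(lambda: day)

    @classmethod
    def system(cls) -> "Clock":
        return cls(dt.date.today)


def tank_status(
    dob: dt.date, state: LifecycleState, on: dt.date
) -> StatusColor:
    """Classify a tank's status colour on date *on*.

    Retired/euthanized tanks are black whatever their age; otherwise the
    colour follows the age thresholds (14 / 90 / 365 days, lower bound
    inclusive for the later class).
    """
    if on < dob:
        raise DomainError(f"status date {on} precedes date of birth {dob}")
    if state in TERMINAL_STATES:
        return StatusColor.BLACK
    age_days = (on - dob).days
    if age_days < AGE_YELLOW_DAYS:
        return StatusColor.WHITE
    if age_days < AGE_GREEN_DAYS:
        return StatusColor.YELLOW
    if age_days < AGE_RED_DAYS:
        return StatusColor.GREEN
    return StatusColor.RED


def cross_color(start: dt.date, retired: bool, on: dt.date) -> CrossColor:
    """Colour a cross: green under a day old, red after, gray once retired."""
    if on < start:
        raise DomainError(f"status date {on} precedes cross start {start}")
    if retired:
        return CrossColor.GRAY
    if (on - start).days < 1:
        return CrossColor.GREEN
    return CrossColor.RED


def sex_display(s: SexComposition) -> str:
    """Display colour for a tank's sex composition.

    Blue for all-male, pink for all-female, purple for mixed, neutral when
    no fish have been sexed.
    """
    if s.males > 0 and s.females == 0:
        return "blue"
    if s.females > 0 and s.males == 0:
        return "pink"
    if s.males > 0 and s.females > 0:
        return "purple"
    return "neutral"


def turnover_date(dob: dt.date) -> dt.date:
    """Scheduled line-turnover date: one calendar year after birth.

    A Feb 29 birth date maps to Feb 28 of the following year.
    """
    try:
        return dob.replace(year=dob.year + 1)
    except ValueError:  # Feb 29 -> Feb 28
        return dob.replace(year=dob.year + 1, day=28)
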