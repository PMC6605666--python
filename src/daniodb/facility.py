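"""Virtual facility: facilities, rooms, racks, and tank placement.

A facility defines a catalog of tank types (each with a width in rack
"spaces"), contains named rooms, and each room holds numbered racks. A
rack is a set of lettered rows; each row has a capacity in spaces equal
to ``n_tanks * spaces_per_tank``. A placed tank claims a contiguous span
of columns (1-based, one column per space) whose width is the
``spaces_occupied`` of its tank type. Spans within a row never overlap.

Facility and room names are immutable once any tank references them:
locations are stored by name, so a silent rename would orphan records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING, Iterable, Optional

from .core import DomainError, StatusColor, tank_status

if TYPE_CHECKING:  # pragma: no cover
    from .store import ColonyStore

__all__ = [
    "TankTypeSpec",
    "RowSpec",
    "RackLayout",
    "Rack",
    "Room",
    "Facility",
    "Position",
    "Span",
    "configure_facility",
    "add_room",
    "rename_room",
    "add_rack",
    "place_tank",
    "locate_tank",
    "move_tank",
    "remove_tank",
    "rack_census",
    "coordinate_labels",
    "preset_layout",
    "preset_names",
]

_ROW_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class TankTypeSpec:
    """A tank size class ("5L") and the rack spaces one tank occupies."""

    label: str
    spaces_occupied: int

    def __post_init__(self) -> None:
        if not self.label:
            raise DomainError("tank-type label must be nonempty")
        if self.spaces_occupied < 1:
            raise DomainError(
                f"tank type {self.label!r}: spaces occupied must be positive"
            )


@dataclass(frozen=True)
class RowSpec:
    """One rack row: its letter, tank slots, and spaces per tank slot."""

    label: str
    n_tanks: int
    spaces_per_tank: int

    def __post_init__(self) -> None:
        if self.n_tanks < 1 or self.spaces_per_tank < 1:
            raise DomainError("row tank and space counts must be positive")

    @property
    def capacity(self) -> int:
        """Row capacity in spaces (columns)."""
        return self.n_tanks * self.spaces_per_tank


@dataclass(frozen=True)
class RackLayout:
    rows: tuple[RowSpec, ...]
    preset_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise DomainError("rack layout needs at least one row")
        expected = list(_ROW_LETTERS[: len(self.rows)])
        got = [r.label for r in self.rows]
        if got != expected:
            raise DomainError(
                f"row labels must be consecutive letters {expected}, got {got}"
            )

    @classmethod
    def custom(cls, rows: Iterable[tuple[int, int]]) -> "RackLayout":
        """Build a layout from (n_tanks, spaces_per_tank) pairs, rows A, B, ..."""
        specs = tuple(
            RowSpec(_ROW_LETTERS[i], n, s) for i, (n, s) in enumerate(rows)
        )
        return cls(specs, preset_name="Custom")

    @property
    def capacity(self) -> int:
        return sum(r.capacity for r in self.rows)

    def row(self, label: str) -> RowSpec:
        for r in self.rows:
            if r.label == label:
                return r
        raise DomainError(f"no row {label!r} in rack layout")


@dataclass(frozen=True)
class Span:
    """A claimed run of columns in one row: [start, start + width - 1]."""

    row: str
    start: int
    width: int

    @property
    def end(self) -> int:
        return self.start + self.width - 1

    def overlaps(self, other: "Span") -> bool:
        return self.row == other.row and not (
            self.end < other.start or other.end < self.start
        )


@dataclass
class Rack:
    index: int  # 1-based, by insertion order, immutable
    layout: RackLayout
    #: rendered TUID -> claimed span
    occupancy: dict[str, Span] = field(default_factory=dict)

    @property
    def occupied_spaces(self) -> int:
        return sum(s.width for s in self.occupancy.values())

    @property
    def free_spaces(self) -> int:
        return self.layout.capacity - self.occupied_spaces


@dataclass
class Room:
    name: str
    facility_name: str
    racks: list[Rack] = field(default_factory=list)
    administrators: list[str] = field(default_factory=list)


@dataclass
class Facility:
    name: str
    tank_types: list[TankTypeSpec] = field(default_factory=list)
    rooms: dict[str, Room] = field(default_factory=dict)

    def tank_type(self, label: str) -> TankTypeSpec:
        for t in self.tank_types:
            if t.label == label:
                return t
        raise DomainError(f"tank type {label!r} not in facility catalog")


@dataclass(frozen=True)
class Position:
    """A rack coordinate: room, rack index, row letter, 1-based column."""

    room: str
    rack_index: int
    row: str
    column: int

    def path(self, facility: str) -> str:
        return (
            f"{facility} / Room {self.room} / Rack {self.rack_index} / "
            f"Row {self.row}, position {self.column}"
        )


# ---------------------------------------------------------------------------
# Vendor rack presets
#
# The commercial vendors (Tecniplast, Aquaneering, Pentair) do not publish a
# single canonical grid; the shipped presets are editable placeholders in
# rack_presets.json (package data) that administrators should adjust to the
# racks actually installed.
# ---------------------------------------------------------------------------


def _load_presets() -> dict[str, list[tuple[int, int]]]:
    text = resources.files("daniodb").joinpath("rack_presets.json").read_text()
    raw = json.loads(text)
    return {
        name: [(r["n_tanks"], r["spaces_per_tank"]) for r in rows]
        for name, rows in raw["presets"].items()
    }


def preset_names() -> list[str]:
    return sorted(_load_presets())


def preset_layout(name: str) -> RackLayout:
    """Look up a shipped vendor rack preset by name (case-insensitive)."""
    presets = _load_presets()
    for key, rows in presets.items():
        if key.lower() == name.lower():
            layout = RackLayout.custom(rows)
            return RackLayout(layout.rows, preset_name=key)
    raise DomainError(
        f"unknown rack preset {name!r}; available: {sorted(presets)}"
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def configure_facility(
    store: "ColonyStore", name: str, tank_types: Iterable[TankTypeSpec]
) -> Facility:
    """Create a facility with its (immutable) tank-type catalog."""
    if name in store.facilities:
        raise DomainError(f"facility {name!r} already exists")
    types = list(tank_types)
    labels = [t.label for t in types]
    if len(set(labels)) != len(labels):
        raise DomainError(f"duplicate tank-type labels in {labels}")
    fac = Facility(name=name, tank_types=types)
    store.facilities[name] = fac
    return fac


def add_room(store: "ColonyStore", facility: str, name: str) -> Room:
    fac = store.facility(facility)
    if name in fac.rooms:
        raise DomainError(f"room {name!r} already exists in {facility!r}")
    room = Room(name=name, facility_name=facility)
    fac.rooms[name] = room
    return room


def rename_room(
    store: "ColonyStore", facility: str, old: str, new: str
) -> Room:
    """Rename a room — rejected once any tank location references it."""
    fac = store.facility(facility)
    if old not in fac.rooms:
        raise DomainError(f"no room {old!r} in {facility!r}")
    if new in fac.rooms:
        raise DomainError(f"room {new!r} already exists in {facility!r}")
    referenced = any(
        t.location is not None and t.location.room == old
        for t in store.tanks.values()
    )
    if referenced:
        raise DomainError(
            f"room {old!r} is referenced by placed tanks and cannot be renamed"
        )
    room = fac.rooms.pop(old)
    room.name = new
    fac.rooms[new] = room
    return room


def add_rack(store: "ColonyStore", facility: str, room: str, layout: RackLayout) -> Rack:
    """Append a rack to a room; rack indices are 1-based insertion order."""
    rm = store.room(facility, room)
    rack = Rack(index=len(rm.racks) + 1, layout=layout)
    rm.racks.append(rack)
    return rack


def _rack_at(store: "ColonyStore", facility: str, pos_room: str, rack_index: int) -> Rack:
    rm = store.room(facility, pos_room)
    if not 1 <= rack_index <= len(rm.racks):
        raise DomainError(
            f"room {pos_room!r} has no rack {rack_index} "
            f"({len(rm.racks)} racks present)"
        )
    return rm.racks[rack_index - 1]


def _span_for(store: "ColonyStore", facility: str, tuid: str, pos: Position) -> tuple[Rack, Span]:
    tank = store.tank(tuid)
    fac = store.facility(facility)
    width = fac.tank_type(tank.tank_type).spaces_occupied
    rack = _rack_at(store, facility, pos.room, pos.rack_index)
    row = rack.layout.row(pos.row)
    span = Span(pos.row, pos.column, width)
    if pos.column < 1 or span.end > row.capacity:
        raise DomainError(
            f"out of range: span {span.start}-{span.end} exceeds row "
            f"{pos.row} capacity {row.capacity}"
        )
    return rack, span


def place_tank(store: "ColonyStore", tuid: str, pos: Position, facility: Optional[str] = None) -> None:
    """Place an active, unplaced tank at a rack coordinate."""
    tank = store.tank(tuid)
    facility = facility or store.default_facility_name()
    if tank.location is not None:
        raise DomainError(f"tank {tuid} already placed; use move_tank")
    rack, span = _span_for(store, facility, tuid, pos)
    for other, taken in rack.occupancy.items():
        if span.overlaps(taken):
            raise DomainError(
                f"occupied: columns {taken.start}-{taken.end} of row "
                f"{taken.row} held by {other}"
            )
    rack.occupancy[tuid] = span
    tank.location = pos
    tank.facility_name = facility


def locate_tank(store: "ColonyStore", tuid: str) -> tuple[Position, str]:
    """Return a placed tank's position and its human-readable facility path."""
    tank = store.tank(tuid)
    if tank.location is None:
        raise DomainError(f"tank {tuid} is not on a rack")
    pos = tank.location
    return pos, pos.path(tank.facility_name)


def move_tank(store: "ColonyStore", tuid: str, new_pos: Position, facility: Optional[str] = None) -> None:
    """Atomically move a placed tank; on any error the old span is kept."""
    tank = store.tank(tuid)
    if tank.location is None:
        raise DomainError(f"tank {tuid} is not on a rack; use place_tank")
    facility = facility or tank.facility_name
    old_rack = _rack_at(store, tank.facility_name, tank.location.room, tank.location.rack_index)
    new_rack, span = _span_for(store, facility, tuid, new_pos)
    old_span = old_rack.occupancy[tuid]
    if new_rack is old_rack and span == old_span:
        return  # no-op move onto own span
    for other, taken in new_rack.occupancy.items():
        if other != tuid and span.overlaps(taken):
            raise DomainError(
                f"occupied: columns {taken.start}-{taken.end} of row "
                f"{taken.row} held by {other}"
            )
    del old_rack.occupancy[tuid]
    new_rack.occupancy[tuid] = span
    tank.location = new_pos
    tank.facility_name = facility


def remove_tank(store: "ColonyStore", tuid: str) -> None:
    """Free a tank's span (used when a tank is retired or euthanized)."""
    tank = store.tank(tuid)
    if tank.location is None:
        return
    rack = _rack_at(store, tank.facility_name, tank.location.room, tank.location.rack_index)
    rack.occupancy.pop(tuid, None)
    tank.location = None


def rack_census(
    store: "ColonyStore", facility: str, room: str, rack_index: int
) -> dict:
    """Status-colour counts plus free/occupied spaces for one rack."""
    rack = _rack_at(store, facility, room, rack_index)
    today = store.clock.today()
    counts = {c: 0 for c in StatusColor}
    for tuid in rack.occupancy:
        tank = store.tank(tuid)
        counts[tank_status(tank.dob, tank.state, today)] += 1
    return {
        "status_counts": counts,
        "tanks": len(rack.occupancy),
        "occupied_spaces": rack.occupied_spaces,
        "free_spaces": rack.free_spaces,
        "capacity": rack.layout.capacity,
    }


def coordinate_labels(
    store: "ColonyStore", facility: str, room: str, rack_index: int, row: str
) -> list[dict]:
    """Barcode label payloads for every position of one rack row.

    Each payload carries the full facility path and a Code 39-safe
    barcode text ``ROOM-RACK-ROWCOLUMN``.
    """
    rack = _rack_at(store, facility, room, rack_index)
    spec = rack.layout.row(row)  # raises on unknown row
    payloads = []
    for col in range(1, spec.capacity + 1):
        payloads.append(
            {
                "facility": facility,
                "room": room,
                "rack": rack_index,
                "row": row,
                "column": col,
                "barcode_text": f"{room}-{rack_index}-{row}{col}".upper(),
            }
        )
    return payloads
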