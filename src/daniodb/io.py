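"""Persistence, import/export, barcodes, labels, backups, demo colony.

The store is persisted as a single-file SQLite database with one table
per record kind; scalar fields are real columns on the key tables and
nested structure (rack occupancy, mating units, readings) is stored as
JSON documents, so the file stays portable and inspectable with the
stock ``sqlite3`` shell.

Barcode payloads use Code 39, the discrete symbology over uppercase
letters, digits and a few symbols, delimited by ``*`` sentinels — every
identifier this package issues is within its alphabet.
"""

from __future__ import annotations

import csv
import datetime as dt
import io as _io
import json
import os
import random
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .access import Lab, Role, User, add_lab, add_user, visible_records
from .core import (
    BACKUP_RETENTION,
    Clock,
    DomainError,
    LifecycleState,
    SerialRegistry,
    SexComposition,
    sex_display,
)
from .facility import (
    Facility,
    Position,
    Rack,
    RackLayout,
    Room,
    RowSpec,
    Span,
    TankTypeSpec,
    add_rack,
    add_room,
    configure_facility,
    place_tank,
    preset_layout,
)
from .lifecycle import (
    CalendarEvent,
    Cross,
    CrossType,
    FollowUpReport,
    GenotypingProtocol,
    Harvest,
    HarvestResource,
    Line,
    MatingUnit,
    MortalityKind,
    MortalityReport,
    NurseryRecord,
    Tank,
    create_harvest,
    create_resources,
    create_tank,
    graduate,
    raise_fry,
    register_line,
    report_dead,
    retire_cross,
    set_up_cross,
    add_follow_up,
)
from .reporting import WATER_PARAMETERS, WaterQualityRecord, ingest_water_quality
from .store import SCHEMA_VERSION, ColonyStore

__all__ = [
    "ColonyStore",
    "LineImportRow",
    "ImportReport",
    "LabelPayload",
    "Code39Symbol",
    "BackupSet",
    "save",
    "load",
    "dump_state",
    "import_lines",
    "export_records",
    "encode_code39",
    "decode_code39",
    "render_label",
    "snapshot",
    "generate_demo_colony",
]

# ---------------------------------------------------------------------------
# Serialization to/from JSON-safe dictionaries
# ---------------------------------------------------------------------------


def _d(x: Optional[dt.date]) -> Optional[str]:
    return x.isoformat() if x is not None else None


def _pd(x: Optional[str]) -> Optional[dt.date]:
    return dt.date.fromisoformat(x) if x is not None else None


def _pos_dict(p: Optional[Position]) -> Optional[dict]:
    if p is None:
        return None
    return {"room": p.room, "rack_index": p.rack_index, "row": p.row, "column": p.column}


def _pos_from(d: Optional[dict]) -> Optional[Position]:
    return Position(**d) if d else None


def _tank_dict(t: Tank) -> dict:
    return {
        "tuid": t.tuid,
        "line": t.line,
        "user": t.user,
        "dob": _d(t.dob),
        "tank_type": t.tank_type,
        "fish_count": t.fish_count,
        "sex": {"males": t.sex.males, "females": t.sex.females, "unsexed": t.sex.unsexed},
        "turnover": _d(t.turnover),
        "sire_tuid": t.sire_tuid,
        "dam_tuid": t.dam_tuid,
        "origin_cuid": t.origin_cuid,
        "state": t.state.value,
        "location": _pos_dict(t.location),
        "facility_name": t.facility_name,
        "created": _d(t.created),
    }


def _tank_from(d: dict) -> Tank:
    return Tank(
        tuid=d["tuid"],
        line=d["line"],
        user=d["user"],
        dob=_pd(d["dob"]),
        tank_type=d["tank_type"],
        fish_count=d["fish_count"],
        sex=SexComposition(**d["sex"]),
        turnover=_pd(d["turnover"]),
        sire_tuid=d["sire_tuid"],
        dam_tuid=d["dam_tuid"],
        origin_cuid=d["origin_cuid"],
        state=LifecycleState(d["state"]),
        location=_pos_from(d["location"]),
        facility_name=d["facility_name"],
        created=_pd(d["created"]),
    )


def _facility_dict(f: Facility) -> dict:
    return {
        "name": f.name,
        "tank_types": [
            {"label": t.label, "spaces_occupied": t.spaces_occupied}
            for t in f.tank_types
        ],
        "rooms": [
            {
                "name": r.name,
                "administrators": list(r.administrators),
                "racks": [
                    {
                        "index": rack.index,
                        "preset_name": rack.layout.preset_name,
                        "rows": [
                            {
                                "label": row.label,
                                "n_tanks": row.n_tanks,
                                "spaces_per_tank": row.spaces_per_tank,
                            }
                            for row in rack.layout.rows
                        ],
                        "occupancy": {
                            tuid: {"row": s.row, "start": s.start, "width": s.width}
                            for tuid, s in rack.occupancy.items()
                        },
                    }
                    for rack in r.racks
                ],
            }
            for r in f.rooms.values()
        ],
    }


def _facility_from(d: dict) -> Facility:
    fac = Facility(
        name=d["name"],
        tank_types=[TankTypeSpec(**t) for t in d["tank_types"]],
    )
    for rd in d["rooms"]:
        room = Room(name=rd["name"], facility_name=d["name"])
        room.administrators = list(rd["administrators"])
        for kd in rd["racks"]:
            layout = RackLayout(
                tuple(RowSpec(**row) for row in kd["rows"]),
                preset_name=kd["preset_name"],
            )
            rack = Rack(index=kd["index"], layout=layout)
            rack.occupancy = {
                tuid: Span(**span) for tuid, span in kd["occupancy"].items()
            }
            room.racks.append(rack)
        fac.rooms[room.name] = room
    return fac


def _cross_dict(c: Cross) -> dict:
    return {
        "cuid": c.cuid,
        "sire_tuid": c.sire_tuid,
        "dam_tuid": c.dam_tuid,
        "type": c.type.value,
        "units": [
            {"unit_index": u.unit_index, "males": u.males, "females": u.females}
            for u in c.units
        ],
        "start": _d(c.start),
        "user": c.user,
        "line": c.line,
        "end": _d(c.end),
        "retired": c.retired,
        "success": c.success,
        "notes": c.notes,
    }


def _cross_from(d: dict) -> Cross:
    return Cross(
        cuid=d["cuid"],
        sire_tuid=d["sire_tuid"],
        dam_tuid=d["dam_tuid"],
        type=CrossType(d["type"]),
        units=[MatingUnit(**u) for u in d["units"]],
        start=_pd(d["start"]),
        user=d["user"],
        line=d["line"],
        end=_pd(d["end"]),
        retired=d["retired"],
        success=d["success"],
        notes=d["notes"],
    )


def _simple_dict(obj, date_fields: tuple[str, ...] = ()) -> dict:
    from dataclasses import asdict

    d = asdict(obj)
    for f in date_fields:
        if d.get(f) is not None:
            d[f] = d[f].isoformat()
    return d


def dump_state(store: ColonyStore) -> dict:
    """The store's full contents as one JSON-safe dictionary.

    This is the canonical structural form: persistence writes it and
    structural equality of two stores is equality of their dumps.
    """
    return {
        "schema_version": store.schema_version,
        "seed": store.seed,
        "registry": dict(store.registry.next_serial),
        "labs": [_simple_dict(x, ("iacuc_expiry",)) for x in store.labs.values()],
        "users": [
            {**_simple_dict(u), "role": u.role.value} for u in store.users.values()
        ],
        "facilities": [_facility_dict(f) for f in store.facilities.values()],
        "lines": [_simple_dict(x) for x in store.lines.values()],
        "protocols": [_simple_dict(x) for x in store.protocols.values()],
        "tanks": [_tank_dict(t) for t in store.tanks.values()],
        "crosses": [_cross_dict(c) for c in store.crosses.values()],
        "nursery": [_simple_dict(x, ("dob",)) for x in store.nursery.values()],
        "harvests": [
            {**_simple_dict(h, ("date",))} for h in store.harvests.values()
        ],
        "mortality_reports": [
            {**_simple_dict(r, ("date",)), "kind": r.kind.value}
            for r in store.mortality_reports
        ],
        "follow_ups": [_simple_dict(x, ("date",)) for x in store.follow_ups],
        "events": [_simple_dict(x, ("date",)) for x in store.events],
        "water_quality": [_simple_dict(x) for x in store.water_quality],
    }


def _restore_state(state: dict, clock: Optional[Clock] = None) -> ColonyStore:
    store = ColonyStore(clock=clock or Clock.system())
    store.schema_version = state["schema_version"]
    store.seed = state["seed"]
    store.registry = SerialRegistry(dict(state["registry"]))
    for d in state["labs"]:
        d = dict(d)
        d["iacuc_expiry"] = _pd(d["iacuc_expiry"])
        store.labs[d["name"]] = Lab(**d)
    for d in state["users"]:
        d = dict(d)
        d["role"] = Role(d["role"])
        store.users[d["name"]] = User(**d)
    for d in state["facilities"]:
        store.facilities[d["name"]] = _facility_from(d)
    for d in state["lines"]:
        line = Line(**d)
        store.lines[line.luid] = line
    for d in state["protocols"]:
        d = dict(d)
        d["primers"] = [tuple(p) for p in d["primers"]]
        d["expected_product_sizes"] = [tuple(p) for p in d["expected_product_sizes"]]
        store.protocols[d["name"]] = GenotypingProtocol(**d)
    for d in state["tanks"]:
        store.tanks[d["tuid"]] = _tank_from(d)
    for d in state["crosses"]:
        store.crosses[d["cuid"]] = _cross_from(d)
    for d in state["nursery"]:
        d = dict(d)
        d["dob"] = _pd(d["dob"])
        store.nursery[d["nuid"]] = NurseryRecord(**d)
    for d in state["harvests"]:
        d = dict(d)
        d["date"] = _pd(d["date"])
        d["resources"] = [HarvestResource(**r) for r in d["resources"]]
        store.harvests[d["huid"]] = Harvest(**d)
    for d in state["mortality_reports"]:
        d = dict(d)
        d["date"] = _pd(d["date"])
        d["kind"] = MortalityKind(d["kind"])
        store.mortality_reports.append(MortalityReport(**d))
    for d in state["follow_ups"]:
        d = dict(d)
        d["date"] = _pd(d["date"])
        store.follow_ups.append(FollowUpReport(**d))
    for d in state["events"]:
        d = dict(d)
        d["date"] = _pd(d["date"])
        store.events.append(CalendarEvent(**d))
    for d in state["water_quality"]:
        d = dict(d)
        d["readings"] = [(int(a), float(b)) for a, b in d["readings"]]
        store.water_quality.append(WaterQualityRecord(**d))
    return store


# ---------------------------------------------------------------------------
# SQLite persistence
# ---------------------------------------------------------------------------

_TABLES: dict[str, str] = {
    "labs": "name",
    "users": "name",
    "facilities": "name",
    "lines": "luid",
    "protocols": "name",
    "tanks": "tuid",
    "crosses": "cuid",
    "nursery": "nuid",
    "harvests": "huid",
}
_LIST_TABLES = ("mortality_reports", "follow_ups", "events", "water_quality")


def save(store: ColonyStore, path: Union[str, Path]) -> None:
    """Write the store to a single-file SQLite database (atomic rewrite)."""
    path = Path(path)
    state = dump_state(store)
    tmp = path.with_suffix(path.suffix + ".tmp")
    if tmp.exists():
        tmp.unlink()
    con = sqlite3.connect(tmp)
    try:
        cur = con.cursor()
        cur.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")
        cur.execute(
            "INSERT INTO meta VALUES ('schema_version', ?)",
            (str(state["schema_version"]),),
        )
        cur.execute(
            "INSERT INTO meta VALUES ('seed', ?)",
            (json.dumps(state["seed"]),),
        )
        cur.execute(
            "CREATE TABLE registry (prefix TEXT PRIMARY KEY, next_serial INTEGER)"
        )
        cur.executemany(
            "INSERT INTO registry VALUES (?, ?)",
            sorted(state["registry"].items()),
        )
        for table, key in _TABLES.items():
            cur.execute(
                f"CREATE TABLE {table} (id TEXT PRIMARY KEY, doc TEXT NOT NULL)"
            )
            cur.executemany(
                f"INSERT INTO {table} VALUES (?, ?)",
                [(d[key], json.dumps(d, sort_keys=True)) for d in state[table]],
            )
        for table in _LIST_TABLES:
            cur.execute(
                f"CREATE TABLE {table} "
                "(seq INTEGER PRIMARY KEY, doc TEXT NOT NULL)"
            )
            cur.executemany(
                f"INSERT INTO {table} VALUES (?, ?)",
                [
                    (i, json.dumps(d, sort_keys=True))
                    for i, d in enumerate(state[table])
                ],
            )
        con.commit()
    finally:
        con.close()
    os.replace(tmp, path)


def load(path: Union[str, Path], clock: Optional[Clock] = None) -> ColonyStore:
    """Load a store saved by :func:`save`, checking referential integrity."""
    path = Path(path)
    if not path.exists():
        raise DomainError(f"no store file at {path}")
    con = sqlite3.connect(path)
    try:
        cur = con.cursor()
        meta = dict(cur.execute("SELECT key, value FROM meta"))
        state: dict = {
            "schema_version": int(meta["schema_version"]),
            "seed": json.loads(meta["seed"]),
            "registry": {
                p: n for p, n in cur.execute("SELECT prefix, next_serial FROM registry")
            },
        }
        for table in _TABLES:
            state[table] = [
                json.loads(doc)
                for (doc,) in cur.execute(f"SELECT doc FROM {table} ORDER BY rowid")
            ]
        for table in _LIST_TABLES:
            state[table] = [
                json.loads(doc)
                for (doc,) in cur.execute(f"SELECT doc FROM {table} ORDER BY seq")
            ]
    finally:
        con.close()
    store = _restore_state(state, clock=clock)
    _check_integrity(store)
    return store


def _check_integrity(store: ColonyStore) -> None:
    """Every reference must resolve; raised on load of a corrupt file."""
    for tank in store.tanks.values():
        if tank.user not in store.users:
            raise DomainError(f"tank {tank.tuid} references unknown user {tank.user!r}")
        for parent in (tank.sire_tuid, tank.dam_tuid):
            if parent is not None and parent not in store.tanks:
                raise DomainError(
                    f"tank {tank.tuid} references unknown parent {parent!r}"
                )
    for cross in store.crosses.values():
        for parent in (cross.sire_tuid, cross.dam_tuid):
            if parent not in store.tanks:
                raise DomainError(
                    f"cross {cross.cuid} references unknown tank {parent!r}"
                )
    for rec in store.nursery.values():
        if rec.cuid not in store.crosses:
            raise DomainError(f"nursery {rec.nuid} references unknown cross {rec.cuid!r}")
    for user in store.users.values():
        if user.lab not in store.labs:
            raise DomainError(f"user {user.name!r} references unknown lab {user.lab!r}")


# ---------------------------------------------------------------------------
# Line import / record export
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineImportRow:
    locus: str
    allele_name: str
    lab_of_origin: str = ""
    general_notes: str = ""


@dataclass
class ImportReport:
    created: list[str] = field(default_factory=list)  # LUIDs
    duplicate_skipped: list[int] = field(default_factory=list)  # row numbers
    invalid: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)

    @property
    def n_created(self) -> int:
        return len(self.created)


#: Import header names (case-insensitive match).
LINE_IMPORT_COLUMNS = ("locus", "allele name", "lab of origin", "general notes")


def import_lines(store: ColonyStore, source: Union[str, Path, _io.TextIOBase]) -> ImportReport:
    """Import lines from a tab-delimited file with a header row.

    Columns are mapped by header name, case-insensitively: Locus, Allele
    Name, Lab of Origin, General Notes. The header row is never imported
    as data. A missing column aborts before any insert; a bad data row is
    skipped with its reason while the other rows proceed.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\t" not in source and "\n" not in source
    ):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    rows = list(csv.reader(_io.StringIO(text), delimiter="\t"))
    if not rows:
        raise DomainError("empty import file: header row required")
    header = [h.strip().lower() for h in rows[0]]
    try:
        col = {name: header.index(name) for name in LINE_IMPORT_COLUMNS}
    except ValueError:
        missing = [n for n in LINE_IMPORT_COLUMNS if n not in header]
        raise DomainError(
            f"missing required column(s) {missing}; found header {rows[0]}"
        ) from None
    report = ImportReport()
    for row_number, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue  # blank line

        def cell(name: str) -> str:
            idx = col[name]
            return row[idx].strip() if idx < len(row) else ""

        parsed = LineImportRow(
            locus=cell("locus"),
            allele_name=cell("allele name"),
            lab_of_origin=cell("lab of origin"),
            general_notes=cell("general notes"),
        )
        if not parsed.locus or not parsed.allele_name:
            report.invalid.append(
                (row_number, "locus and allele name must be nonempty")
            )
            continue
        duplicate = any(
            ln.locus == parsed.locus and ln.allele_name == parsed.allele_name
            for ln in store.lines.values()
        )
        if duplicate:
            report.duplicate_skipped.append(row_number)
            continue
        line = register_line(
            store,
            locus=parsed.locus,
            allele_name=parsed.allele_name,
            lab_of_origin=parsed.lab_of_origin,
            notes=parsed.general_notes,
        )
        report.created.append(line.luid)
    return report


_EXPORT_COLUMNS = {
    "line": ["Locus", "Allele Name", "Lab of Origin", "General Notes"],
    "tank": [
        "TUID", "Line", "User", "DOB", "Tank Type", "Fish Count",
        "Males", "Females", "Unsexed", "State", "Turnover",
    ],
    "cross": ["CUID", "Sire", "Dam", "Type", "Units", "Start", "End", "Retired"],
}


def export_records(
    store: ColonyStore,
    kind: str,
    format: str = "tsv",
    as_user: Optional[str] = None,
) -> str:
    """Export records of one kind as TSV/CSV text.

    Line exports use the same columns the importer reads, so an
    export→import round-trip reproduces the line set. With *as_user*,
    only records visible to that user are exported.
    """
    if kind not in _EXPORT_COLUMNS:
        raise DomainError(f"unsupported export kind {kind!r}")
    if format not in ("tsv", "csv"):
        raise DomainError(f"unsupported export format {format!r}")
    if as_user is not None:
        records = visible_records(store, as_user, kind)
    else:
        records = {
            "line": list(store.lines.values()),
            "tank": list(store.tanks.values()),
            "cross": list(store.crosses.values()),
        }[kind]
    out = _io.StringIO()
    writer = csv.writer(out, delimiter="\t" if format == "tsv" else ",", lineterminator="\n")
    writer.writerow(_EXPORT_COLUMNS[kind])
    for r in records:
        if kind == "line":
            writer.writerow([r.locus, r.allele_name, r.lab_of_origin, r.notes])
        elif kind == "tank":
            writer.writerow(
                [
                    r.tuid, r.line, r.user, r.dob.isoformat(), r.tank_type,
                    r.fish_count, r.sex.males, r.sex.females, r.sex.unsexed,
                    r.state.value, r.turnover.isoformat(),
                ]
            )
        else:
            writer.writerow(
                [
                    r.cuid, r.sire_tuid, r.dam_tuid, r.type.value, len(r.units),
                    r.start.isoformat(), _d(r.end) or "", r.retired,
                ]
            )
    return out.getvalue()


# ---------------------------------------------------------------------------
# Code 39 barcodes
# ---------------------------------------------------------------------------

# Standard 9-element wide/narrow patterns (bars and spaces interleaved,
# exactly three wide elements per symbol); '*' is the start/stop sentinel.
_CODE39_PATTERNS = {
    "0": "nnnwwnwnn", "1": "wnnwnnnnw", "2": "nnwwnnnnw", "3": "wnwwnnnnn",
    "4": "nnnwwnnnw", "5": "wnnwwnnnn", "6": "nnwwwnnnn", "7": "nnnwnnwnw",
    "8": "wnnwnnwnn", "9": "nnwwnnwnn", "A": "wnnnnwnnw", "B": "nnwnnwnnw",
    "C": "wnwnnwnnn", "D": "nnnnwwnnw", "E": "wnnnwwnnn", "F": "nnwnwwnnn",
    "G": "nnnnnwwnw", "H": "wnnnnwwnn", "I": "nnwnnwwnn", "J": "nnnnwwwnn",
    "K": "wnnnnnnww", "L": "nnwnnnnww", "M": "wnwnnnnwn", "N": "nnnnwnnww",
    "O": "wnnnwnnwn", "P": "nnwnwnnwn", "Q": "nnnnnnwww", "R": "wnnnnnwwn",
    "S": "nnwnnnwwn", "T": "nnnnwnwwn", "U": "wwnnnnnnw", "V": "nwwnnnnnw",
    "W": "wwwnnnnnn", "X": "nwnnwnnnw", "Y": "wwnnwnnnn", "Z": "nwwnwnnnn",
    "-": "nwnnnnwnw", ".": "wwnnnnwnn", " ": "nwwnnnwnn", "$": "nwnwnwnnn",
    "/": "nwnwnnnwn", "+": "nwnnnwnwn", "%": "nnnwnwnwn", "*": "nwnnwnwnn",
}
_CODE39_REVERSE = {v: k for k, v in _CODE39_PATTERNS.items()}
CODE39_ALPHABET = frozenset(_CODE39_PATTERNS) - {"*"}


@dataclass(frozen=True)
class Code39Symbol:
    payload: str
    encoded: str  # per-character patterns joined by single narrow gaps (spaces)

    @property
    def bars(self) -> str:
        return self.encoded


def encode_code39(payload: str) -> Code39Symbol:
    """Encode a payload in Code 39 with start/stop ``*`` sentinels."""
    if not payload:
        raise DomainError("empty barcode payload")
    for ch in payload:
        if ch not in CODE39_ALPHABET:
            raise DomainError(
                f"character {ch!r} is outside the Code 39 alphabet "
                "(uppercase A-Z, 0-9, '-', '.', ' ', '$', '/', '+', '%')"
            )
    parts = ["*", *payload, "*"]
    encoded = " ".join(_CODE39_PATTERNS[ch] for ch in parts)
    return Code39Symbol(payload=payload, encoded=encoded)


def decode_code39(symbol: Union[Code39Symbol, str]) -> str:
    """Decode a Code 39 bar/space pattern back to its payload."""
    encoded = symbol.encoded if isinstance(symbol, Code39Symbol) else symbol
    patterns = encoded.split(" ")
    if len(patterns) < 2:
        raise DomainError("Code 39 symbol too short: missing sentinels")
    chars = []
    for pat in patterns:
        ch = _CODE39_REVERSE.get(pat)
        if ch is None:
            raise DomainError(f"invalid Code 39 pattern {pat!r}")
        chars.append(ch)
    if chars[0] != "*" or chars[-1] != "*":
        raise DomainError("Code 39 symbol must start and stop with '*'")
    inner = chars[1:-1]
    if "*" in inner:
        raise DomainError("'*' sentinel inside Code 39 payload")
    return "".join(inner)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelPayload:
    """Structured label content; physical layout is left to the printer."""

    label_kind: str  # tank | cross | petri | nursery | rack_coordinate
    fields: tuple[tuple[str, str], ...]
    barcode_text: str

    def field(self, name: str) -> str:
        for key, value in self.fields:
            if key == name:
                return value
        raise KeyError(name)


def _tank_label_fields(store: ColonyStore, tank: Tank) -> list[tuple[str, str]]:
    owner = store.users.get(tank.user)
    lab = store.labs.get(owner.lab) if owner else None
    if tank.location is not None:
        location = (
            f"Room {tank.location.room}, Rack {tank.location.rack_index}, "
            f"Row {tank.location.row}, position {tank.location.column}"
        )
    else:
        location = ""
    return [
        ("tuid", tank.tuid),
        ("genotype", tank.line),
        ("sex", sex_display(tank.sex)),
        ("dob", tank.dob.isoformat()),
        ("owner", tank.user),
        ("iacuc", lab.iacuc_protocol if lab else ""),
        ("location", location),
    ]


def render_label(store: ColonyStore, record_id: str, label_kind: str) -> LabelPayload:
    """Build the label payload for a record; barcode text is its identifier."""
    if label_kind == "tank":
        tank = store.tank(record_id)
        return LabelPayload("tank", tuple(_tank_label_fields(store, tank)), tank.tuid)
    if label_kind == "cross":
        cross = store.cross(record_id)
        fields: list[tuple[str, str]] = [("cuid", cross.cuid), ("owner", cross.user)]
        for role, tuid in (("sire", cross.sire_tuid), ("dam", cross.dam_tuid)):
            parent = store.tank(tuid)
            fields.append((f"{role}_tuid", tuid))
            fields.append((f"{role}_genotype", parent.line))
            if parent.location is not None:
                fields.append(
                    (
                        f"{role}_location",
                        f"{parent.location.room}/R{parent.location.rack_index}/"
                        f"{parent.location.row}{parent.location.column}",
                    )
                )
        return LabelPayload("cross", tuple(fields), cross.cuid)
    if label_kind in ("petri", "nursery"):
        rec = store.nursery_record(record_id)
        cross = store.cross(rec.cuid)
        fields = [
            ("nuid", rec.nuid),
            ("cuid", rec.cuid),
            ("genotype", cross.line),
            ("dob", rec.dob.isoformat()),
            ("count", str(rec.initial_fry)),
            ("owner", cross.user),
        ]
        return LabelPayload(label_kind, tuple(fields), rec.nuid)
    raise DomainError(
        f"label kind {label_kind!r} incompatible with record {record_id!r}"
    )


# ---------------------------------------------------------------------------
# Backups
# ---------------------------------------------------------------------------


@dataclass
class BackupSet:
    """A rotation of store snapshots: at most the last seven are kept."""

    directory: Path
    retention: int = BACKUP_RETENTION

    def snapshots(self) -> list[Path]:
        return sorted(self.directory.glob("snapshot-*.db"))


def snapshot(
    store: ColonyStore,
    directory: Union[str, Path],
    retention: int = BACKUP_RETENTION,
) -> BackupSet:
    """Append a snapshot of the store, evicting the oldest beyond retention.

    The new snapshot is written before anything is evicted, so an I/O
    failure never costs an existing backup; the newest snapshot is never
    the one evicted.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    backup_set = BackupSet(directory, retention)
    existing = backup_set.snapshots()
    if existing:
        last_seq = int(existing[-1].stem.split("-")[1])
    else:
        last_seq = 0
    stamp = store.clock.today().isoformat()
    target = directory / f"snapshot-{last_seq + 1:06d}-{stamp}.db"
    save(store, target)
    for old in backup_set.snapshots()[:-retention]:
        old.unlink()
    return backup_set


def restore(snapshot_path: Union[str, Path], clock: Optional[Clock] = None) -> ColonyStore:
    """Load a snapshot back into a store (alias of :func:`load`)."""
    return load(snapshot_path, clock=clock)


# ---------------------------------------------------------------------------
# Demo colony generator
# ---------------------------------------------------------------------------

_CAUSES = ("old age", "fungal infection", "bacterial infection", "egg-bound", "unknown")
_SYMPTOMS = ("lethargy", "skin lesions", "bloating", "emaciation", "none observed")
_LOCI = ("Tg", "Et", "mn", "sa", "ca")


def generate_demo_colony(
    seed: int,
    n_labs: int = 2,
    n_lines: int = 6,
    n_tanks: int = 50,
    n_crosses: int = 10,
    days: int = 365,
    anchor: dt.date = dt.date(2026, 6, 1),
) -> ColonyStore:
    """Build a seeded pseudo-random colony exercising every record kind.

    ``n_tanks`` is the total number of placed tanks, including the tanks
    created by graduating fry; the simulation spans the *days* before
    *anchor*, which becomes the store clock's "today". The same seed
    always produces an identical store.
    """
    if min(n_labs, n_lines, n_tanks, n_crosses, days) < 0:
        raise DomainError("demo colony counts must be non-negative")
    if n_crosses > 0 and (n_tanks < 3 or n_lines < 1 or n_labs < 1):
        raise DomainError(
            "infeasible demo colony: crosses need at least 3 tanks and a line"
        )
    if n_tanks > 0 and (n_labs < 1 or n_lines < 1):
        raise DomainError("infeasible demo colony: tanks need labs and lines")
    rng = random.Random(seed)
    start = anchor - dt.timedelta(days=days)
    store = ColonyStore(clock=Clock.fixed(start), seed=seed)

    # labs, users (first user of lab 1 is the facility administrator)
    for i in range(1, n_labs + 1):
        add_lab(
            store,
            f"Lab-{i}",
            pi=f"PI {i}",
            institution="Demo University",
            contact=f"lab{i}@example.org",
            iacuc_protocol=f"AN-{1000 + i}",
            iacuc_expiry=anchor + dt.timedelta(days=365),
        )
        add_user(store, f"user{i}a", f"Lab-{i}", email=f"user{i}a@example.org")
        add_user(store, f"user{i}b", f"Lab-{i}", email=f"user{i}b@example.org")
    if n_labs:
        add_user(store, "facility_admin", "Lab-1", role=Role.ADMIN)
    users = [u for u in store.users if u != "facility_admin"]

    # facility geometry: two rooms, two vendor-preset racks each
    configure_facility(
        store,
        "MAIN",
        [
            TankTypeSpec("0.8L", 1),
            TankTypeSpec("2.8L", 1),
            TankTypeSpec("5L", 2),
            TankTypeSpec("10L", 4),
        ],
    )
    for room_name in ("R1", "R2"):
        room = add_room(store, "MAIN", room_name)
        room.administrators = ["facility_admin"] if n_labs else []
        add_rack(store, "MAIN", room_name, preset_layout("Tecniplast"))
        add_rack(store, "MAIN", room_name, preset_layout("Aquaneering"))

    # lines
    for i in range(n_lines):
        register_line(
            store,
            locus=_LOCI[i % len(_LOCI)] + str(i + 1),
            allele_name=f"allele{i + 1:02d}",
            lab_of_origin=f"Lab-{(i % max(n_labs, 1)) + 1}" if n_labs else "",
            zfin_id=f"ZDB-ALT-{200000 + i}",
        )
    alleles = sorted(store.allele_vocabulary())

    # founder tanks (chronological creation; all placed)
    n_graduates = min(2, n_crosses)
    n_founders = n_tanks - n_graduates
    if n_founders < 0:
        raise DomainError("infeasible demo colony: n_tanks smaller than graduates")
    free_anchors = _enumerate_anchor_columns(store)
    dobs = sorted(
        start + dt.timedelta(days=rng.randint(0, max(days - 20, 1)))
        for _ in range(n_founders)
    )
    founders = []
    for dob in dobs:
        store.set_today(dob)
        tank = create_tank(
            store,
            allele_name=rng.choice(alleles),
            user=rng.choice(users),
            dob=dob,
            tank_type=rng.choice(["2.8L", "2.8L", "5L", "0.8L"]),
            sex=SexComposition(
                males=rng.randint(2, 8),
                females=rng.randint(2, 8),
                unsexed=rng.randint(0, 4),
            ),
        )
        _place_on_free_anchor(store, tank.tuid, free_anchors)
        founders.append(tank.tuid)

    # crosses: sire/dam tank-wise; a fixed share retired with success noted
    crosses = []
    for i in range(n_crosses):
        ctype = rng.choice([CrossType.PAIR, CrossType.TRIO, CrossType.BULK])
        n_units = rng.randint(1, 2)
        bulk = (rng.randint(1, 2), rng.randint(1, 2))
        unit_m, unit_f = {
            CrossType.PAIR: (1, 1),
            CrossType.TRIO: (1, 2),
            CrossType.BULK: bulk,
        }[ctype]
        # pick parents whose sex ledgers can supply the mating units
        sires = [t for t in founders if store.tanks[t].sex.males >= n_units * unit_m]
        if not sires:
            n_units = 1
            sires = [t for t in founders if store.tanks[t].sex.males >= unit_m]
        sire = store.tanks[rng.choice(sires)]
        dams = [
            t
            for t in founders
            if t != sire.tuid and store.tanks[t].sex.females >= n_units * unit_f
        ]
        if not dams:
            n_units = 1
            dams = [
                t
                for t in founders
                if t != sire.tuid and store.tanks[t].sex.females >= unit_f
            ]
        dam = store.tanks[rng.choice(dams)]
        latest = max(sire.dob, dam.dob)
        cross_date = min(
            latest + dt.timedelta(days=rng.randint(14, 120)),
            anchor - dt.timedelta(days=6),
        )
        cross_date = max(cross_date, latest)
        store.set_today(cross_date)
        cross = set_up_cross(
            store,
            sire.tuid,
            dam.tuid,
            ctype,
            n_units=n_units,
            bulk_counts=bulk,
        )
        crosses.append(cross)
        if i % 3 != 0:  # two thirds already taken down
            store.set_today(cross_date + dt.timedelta(days=1))
            retire_cross(store, cross.cuid, success=rng.random() < 0.8)

    # fry and graduation (the first two crosses feed the nursery)
    for i, cross in enumerate(crosses[:n_graduates]):
        fry_dob = cross.start
        store.set_today(fry_dob)
        dishes = raise_fry(
            store,
            cross.cuid,
            fry_per_dish=rng.randint(20, 40),
            n_dishes=2,
            dob=fry_dob,
        )
        store.set_today(fry_dob + dt.timedelta(days=5))
        survivors = {
            d.nuid: rng.randint(d.initial_fry // 2, d.initial_fry) for d in dishes
        }
        tank = graduate(store, survivors)
        _place_on_free_anchor(store, tank.tuid, free_anchors)

    # harvests: embryos from a cross, adults from a tank, split resources
    if crosses:
        store.set_today(crosses[0].start)
        h1 = create_harvest(
            store, crosses[0].cuid, quantity=50, treatment="control vs heat shock",
            age_at_collection="24 hpf",
        )
        create_resources(store, h1.huid, [25, 25], ["control", "heat shock"])
    if founders:
        store.set_today(anchor - dt.timedelta(days=10))
        h2 = create_harvest(
            store, founders[0], quantity=4, treatment="fin clip",
            age_at_collection="adult",
        )
        create_resources(store, h2.huid, [2, 2])

    # mortality and follow-ups over the trailing window (never emptying a tank)
    placed = [t for t in store.tanks.values() if t.location is not None]
    for tank in placed:
        if rng.random() < 0.4 and tank.fish_count > 2:
            date = max(
                tank.dob + dt.timedelta(days=1),
                anchor - dt.timedelta(days=rng.randint(1, min(days, 180))),
            )
            store.set_today(date)
            report_dead(
                store,
                tank.tuid,
                n_dead=rng.randint(1, min(2, tank.fish_count - 1)),
                kind=rng.choice(list(MortalityKind)),
                cause=rng.choice(_CAUSES),
                symptom=rng.choice(_SYMPTOMS),
                date=date,
            )
    store.set_today(anchor)
    for tank in placed[:2]:
        if tank.state is LifecycleState.ACTIVE:
            add_follow_up(store, tank.tuid, "check fin damage")

    # water quality for the anchor month, every parameter, rack R1/1
    if store.facilities and store.facility("MAIN").rooms:
        for param in WATER_PARAMETERS:
            base = {"conductivity": 700, "pH": 7.4, "temperature": 28.0,
                    "nitrites": 0.05, "nitrates": 5.0, "chlorine": 0.01}[param]
            readings = []
            for day in range(1, 11):
                for _ in range(rng.randint(1, 3)):
                    readings.append(
                        (day, round(base * (1 + rng.uniform(-0.05, 0.05)), 4))
                    )
            ingest_water_quality(
                store, "MAIN", "R1", 1, anchor.year, anchor.month, param, readings
            )

    store.set_today(anchor)
    return store


def _enumerate_anchor_columns(store: ColonyStore) -> list[tuple[str, int, str, int]]:
    """All (room, rack, row, column) anchors, widest-friendly stride of 1."""
    out = []
    for fac in store.facilities.values():
        for room in fac.rooms.values():
            for rack in room.racks:
                for row in rack.layout.rows:
                    for col in range(1, row.capacity + 1):
                        out.append((room.name, rack.index, row.label, col))
    return out


def _place_on_free_anchor(
    store: ColonyStore, tuid: str, anchors: list[tuple[str, int, str, int]]
) -> None:
    for room, rack, row, col in anchors:
        pos = Position(room=room, rack_index=rack, row=row, column=col)
        try:
            place_tank(store, tuid, pos, facility="MAIN")
            return
        except DomainError:
            continue
    raise DomainError(f"no free rack span for tank {tuid}")
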