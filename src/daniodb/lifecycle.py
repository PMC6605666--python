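"""Husbandry lifecycle: lines, tanks, crosses, nursery, harvests, mortality.

The reproduction chain forms the colony's pedigree: two tanks (TUIDs) are
mated in a cross (CUID); fry raised from the cross live in nursery dishes
(NUIDs) until they graduate — at about day 5 — into a new tank whose
parents are the cross's sire and dam. Harvests (HUIDs) pull embryos from
a cross or adults from a tank and can be split into sub-indexed
experimental resources (H0001-1, H0001-2, ...).

Identifiers are carried on records in rendered string form ("T0370");
the store's :class:`~daniodb.core.SerialRegistry` issues them.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

from .core import (
    GRADUATION_AGE_DAYS,
    DomainError,
    Identifier,
    LifecycleState,
    SexComposition,
    next_uid,
    turnover_date,
)
from .facility import Position, remove_tank

if TYPE_CHECKING:  # pragma: no cover
    from .store import ColonyStore

__all__ = [
    "Line",
    "GenotypingProtocol",
    "Tank",
    "CrossType",
    "MatingUnit",
    "Cross",
    "NurseryRecord",
    "Harvest",
    "HarvestResource",
    "MortalityKind",
    "MortalityReport",
    "FollowUpReport",
    "CalendarEvent",
    "PedigreeNode",
    "register_line",
    "add_genotyping_protocol",
    "create_tank",
    "retire_tank",
    "set_up_cross",
    "retire_cross",
    "raise_fry",
    "graduate",
    "scheduled_graduation_date",
    "create_harvest",
    "create_resources",
    "report_dead",
    "add_follow_up",
    "add_event",
    "due_reminders",
    "pedigree",
    "DEFAULT_BULK_COUNTS",
]

#: Default male/female counts for a bulk mating unit (user-overridable).
DEFAULT_BULK_COUNTS = (5, 5)


@dataclass
class Line:
    """A distinct allele following ZFIN nomenclature.

    The allele name is the controlled-vocabulary key reused by every tank
    and cross; registering a line is what makes the allele available.
    """

    luid: str
    locus: str
    allele_name: str
    nickname: str = ""
    lab_of_origin: str = ""
    zfin_id: str = ""
    originating_strain: str = ""
    pubmed_id: str = ""
    received_from: str = ""
    cloning_notes: str = ""
    notes: str = ""
    attachments: list[str] = field(default_factory=list)
    protocols: list[str] = field(default_factory=list)


@dataclass
class GenotypingProtocol:
    name: str
    zfin_id: str = ""
    primers: list[tuple[str, str]] = field(default_factory=list)
    thermocycler_conditions: str = ""
    expected_product_sizes: list[tuple[str, int]] = field(default_factory=list)
    gel_image: str = ""
    notes: str = ""


@dataclass
class Tank:
    tuid: str
    line: str  # allele name (controlled vocabulary key)
    user: str
    dob: dt.date
    tank_type: str
    fish_count: int
    sex: SexComposition
    turnover: dt.date
    sire_tuid: Optional[str] = None
    dam_tuid: Optional[str] = None
    origin_cuid: Optional[str] = None
    state: LifecycleState = LifecycleState.ACTIVE
    location: Optional[Position] = None
    facility_name: Optional[str] = None
    created: Optional[dt.date] = None


class CrossType(str, enum.Enum):
    PAIR = "pair"
    TRIO = "trio"
    BULK = "bulk"


@dataclass(frozen=True)
class MatingUnit:
    unit_index: int
    males: int
    females: int


@dataclass
class Cross:
    cuid: str
    sire_tuid: str
    dam_tuid: str
    type: CrossType
    units: list[MatingUnit]
    start: dt.date
    user: str
    line: str
    end: Optional[dt.date] = None
    retired: bool = False
    success: Optional[bool] = None
    notes: str = ""


@dataclass
class NurseryRecord:
    nuid: str
    cuid: str
    dob: dt.date
    initial_fry: int
    state: str = "on_nursery"  # on_nursery | graduated | discarded
    graduated_count: Optional[int] = None
    successor_tuid: Optional[str] = None
    # scope snapshot (sire tank's location when the fry were raised)
    facility_name: Optional[str] = None
    room: Optional[str] = None
    rack_index: Optional[int] = None


@dataclass
class HarvestResource:
    resource_id: str  # e.g. "H0001-1"
    sub_index: int
    group_size: int
    condition: str = ""
    genotype_annotation: str = ""
    images: list[str] = field(default_factory=list)


@dataclass
class Harvest:
    huid: str
    source: str  # CUID (embryos) or TUID (adults)
    date: dt.date
    quantity: int
    treatment: str = ""
    age_at_collection: str = ""
    user: str = ""
    resources: list[HarvestResource] = field(default_factory=list)

    @property
    def allocated(self) -> int:
        return sum(r.group_size for r in self.resources)


class MortalityKind(str, enum.Enum):
    FOUND_DEAD = "found_dead"
    EUTHANIZED = "euthanized"


@dataclass
class MortalityReport:
    tank: str
    date: dt.date
    n_dead: int
    kind: MortalityKind
    cause: str
    symptom: str
    notes: str = ""
    # scope snapshot at report time
    facility_name: Optional[str] = None
    room: Optional[str] = None
    rack_index: Optional[int] = None


@dataclass
class FollowUpReport:
    tank: str
    date: dt.date
    note: str
    open: bool = True


@dataclass
class CalendarEvent:
    title: str
    date: dt.date
    facility: Optional[str] = None
    room: Optional[str] = None
    recipients: list[str] = field(default_factory=list)
    origin: str = "manual"  # manual | turnover_auto | graduation_auto
    source_id: Optional[str] = None
    acknowledged: bool = False


# ---------------------------------------------------------------------------
# Lines
# ---------------------------------------------------------------------------


def register_line(store: "ColonyStore", locus: str, allele_name: str, **fields) -> Line:
    """Register an allele; its name enters the controlled vocabulary."""
    if not allele_name:
        raise DomainError("allele name must be nonempty")
    if not locus:
        raise DomainError("locus must be nonempty")
    for line in store.lines.values():
        if line.locus == locus and line.allele_name == allele_name:
            raise DomainError(
                f"line ({locus!r}, {allele_name!r}) already registered as {line.luid}"
            )
    luid = next_uid(store.registry, "L").rendered
    line = Line(luid=luid, locus=locus, allele_name=allele_name, **fields)
    store.lines[luid] = line
    return line


def add_genotyping_protocol(store: "ColonyStore", name: str, **fields) -> GenotypingProtocol:
    if name in store.protocols:
        raise DomainError(f"genotyping protocol {name!r} already exists")
    proto = GenotypingProtocol(name=name, **fields)
    store.protocols[name] = proto
    return proto


# ---------------------------------------------------------------------------
# Tanks
# ---------------------------------------------------------------------------


def create_tank(
    store: "ColonyStore",
    allele_name: str,
    user: str,
    dob: dt.date,
    tank_type: str,
    sex: SexComposition,
    sire_tuid: Optional[str] = None,
    dam_tuid: Optional[str] = None,
    origin_cuid: Optional[str] = None,
    set_turnover_reminder: bool = True,
) -> Tank:
    """Create a tank; its turnover date is one year after date of birth.

    The allele must already be in the line vocabulary and the tank type in
    the facility catalog — both enforce uniform nomenclature. A
    turnover-reminder calendar event is created by default.
    """
    if allele_name not in store.allele_vocabulary():
        raise DomainError(
            f"unknown allele {allele_name!r}: register the line first"
        )
    owner = store.user(user)
    if not owner.active:
        raise DomainError(f"user {user!r} is inactive and cannot own new records")
    today = store.clock.today()
    if dob > today:
        raise DomainError(f"date of birth {dob} is in the future")
    fac = store.facility(store.default_facility_name())
    fac.tank_type(tank_type)  # raises if unknown
    for parent in (sire_tuid, dam_tuid):
        if parent is not None:
            store.tank(parent)
    if origin_cuid is not None:
        store.cross(origin_cuid)
    tuid = next_uid(store.registry, "T").rendered
    tank = Tank(
        tuid=tuid,
        line=allele_name,
        user=user,
        dob=dob,
        tank_type=tank_type,
        fish_count=sex.total,
        sex=sex,
        turnover=turnover_date(dob),
        sire_tuid=sire_tuid,
        dam_tuid=dam_tuid,
        origin_cuid=origin_cuid,
        created=today,
    )
    store.tanks[tuid] = tank
    if set_turnover_reminder:
        store.events.append(
            CalendarEvent(
                title=f"Turn over tank {tuid} ({allele_name})",
                date=tank.turnover,
                recipients=[user],
                origin="turnover_auto",
                source_id=tuid,
            )
        )
    return tank


def retire_tank(
    store: "ColonyStore", tuid: str, state: LifecycleState = LifecycleState.RETIRED
) -> Tank:
    """Retire or euthanize a tank: terminal, and frees its rack span."""
    if state == LifecycleState.ACTIVE:
        raise DomainError("cannot retire a tank to the active state")
    tank = store.tank(tuid)
    if tank.state != LifecycleState.ACTIVE:
        raise DomainError(f"tank {tuid} is already {tank.state.value}")
    remove_tank(store, tuid)
    tank.state = state
    return tank


# ---------------------------------------------------------------------------
# Crosses
# ---------------------------------------------------------------------------

_UNIT_COMPOSITION = {CrossType.PAIR: (1, 1), CrossType.TRIO: (1, 2)}


def set_up_cross(
    store: "ColonyStore",
    sire_tuid: str,
    dam_tuid: str,
    type: CrossType | str,
    n_units: int = 1,
    bulk_counts: tuple[int, int] = DEFAULT_BULK_COUNTS,
) -> Cross:
    """Set up a mating between two tanks.

    A pair unit is one male and one female, a trio one male and two
    females, and a bulk unit is user-specified. Males are drawn from the
    sire tank's sex ledger and females from the dam tank's; fish are
    labelled out, not removed from their home tanks.
    """
    ctype = CrossType(type)
    if n_units < 1:
        raise DomainError("number of mating units must be positive")
    sire = store.tank(sire_tuid)
    dam = store.tank(dam_tuid)
    for label, tank in (("sire", sire), ("dam", dam)):
        if tank.state != LifecycleState.ACTIVE:
            raise DomainError(
                f"inactive parent: {label} tank {tank.tuid} is {tank.state.value}"
            )
    if ctype == CrossType.BULK:
        unit_m, unit_f = bulk_counts
        if unit_m < 1 or unit_f < 1:
            raise DomainError("bulk mating counts must be positive")
    else:
        unit_m, unit_f = _UNIT_COMPOSITION[ctype]
    need_m, need_f = n_units * unit_m, n_units * unit_f
    if sire.sex.males < need_m:
        raise DomainError(
            f"sex composition insufficient: sire tank {sire_tuid} has "
            f"{sire.sex.males} males, {need_m} needed"
        )
    if dam.sex.females < need_f:
        raise DomainError(
            f"sex composition insufficient: dam tank {dam_tuid} has "
            f"{dam.sex.females} females, {need_f} needed"
        )
    cuid = next_uid(store.registry, "C").rendered
    cross = Cross(
        cuid=cuid,
        sire_tuid=sire_tuid,
        dam_tuid=dam_tuid,
        type=ctype,
        units=[MatingUnit(i + 1, unit_m, unit_f) for i in range(n_units)],
        start=store.clock.today(),
        user=sire.user,
        line=sire.line,
    )
    store.crosses[cuid] = cross
    return cross


def retire_cross(
    store: "ColonyStore",
    cuid: str,
    end: Optional[dt.date] = None,
    success: Optional[bool] = None,
    notes: str = "",
) -> Cross:
    """Retire a mating once the pairs are taken down; records fecundity."""
    cross = store.cross(cuid)
    if cross.retired:
        raise DomainError(f"cross {cuid} is already retired")
    cross.retired = True
    cross.end = end or store.clock.today()
    cross.success = success
    if notes:
        cross.notes = notes
    return cross


# ---------------------------------------------------------------------------
# Nursery
# ---------------------------------------------------------------------------


def raise_fry(
    store: "ColonyStore",
    cuid: str,
    fry_per_dish: int,
    n_dishes: int = 1,
    dob: Optional[dt.date] = None,
) -> list[NurseryRecord]:
    """Create nursery records for fry raised from a cross.

    Each dish gets its own NUID; the initial fry counts feed the vitality
    report's births. A day-5 graduation reminder is scheduled per dish.
    """
    cross = store.cross(cuid)
    if fry_per_dish < 1:
        raise DomainError("fry per dish must be positive")
    if n_dishes < 1:
        raise DomainError("number of dishes must be positive")
    dob = dob or store.clock.today()
    sire = store.tank(cross.sire_tuid)
    records = []
    for _ in range(n_dishes):
        nuid = next_uid(store.registry, "N").rendered
        rec = NurseryRecord(
            nuid=nuid,
            cuid=cuid,
            dob=dob,
            initial_fry=fry_per_dish,
            facility_name=sire.facility_name,
            room=sire.location.room if sire.location else None,
            rack_index=sire.location.rack_index if sire.location else None,
        )
        store.nursery[nuid] = rec
        store.events.append(
            CalendarEvent(
                title=f"Graduate fry {nuid} (from {cuid}) to system",
                date=scheduled_graduation_date(rec),
                recipients=[cross.user],
                origin="graduation_auto",
                source_id=nuid,
            )
        )
        records.append(rec)
    return records


def scheduled_graduation_date(nursery: NurseryRecord) -> dt.date:
    """Fry graduate from the nursery to the main system at day 5."""
    return nursery.dob + dt.timedelta(days=GRADUATION_AGE_DAYS)


def graduate(
    store: "ColonyStore",
    graduated_counts: Mapping[str, int],
    tank_type: Optional[str] = None,
) -> Tank:
    """Graduate nursery dishes into one new tank on the main system.

    All NUIDs must come from the same cross (same genotype); the new
    tank's line, owner and parents are inherited from that cross and its
    fish count is the sum of the per-dish survivor counts.
    """
    if not graduated_counts:
        raise DomainError("no nursery records given")
    records = [store.nursery_record(n) for n in graduated_counts]
    cuids = {r.cuid for r in records}
    if len(cuids) > 1:
        raise DomainError(f"genotype mismatch: NUIDs span crosses {sorted(cuids)}")
    for rec in records:
        if rec.state != "on_nursery":
            raise DomainError(f"nursery record {rec.nuid} is already {rec.state}")
        survivors = graduated_counts[rec.nuid]
        if survivors < 0 or survivors > rec.initial_fry:
            raise DomainError(
                f"{rec.nuid}: graduated count {survivors} outside "
                f"[0, {rec.initial_fry}]"
            )
    cross = store.cross(cuids.pop())
    total = sum(graduated_counts.values())
    if tank_type is None:
        fac = store.facility(store.default_facility_name())
        if not fac.tank_types:
            raise DomainError("facility has no tank types configured")
        tank_type = fac.tank_types[0].label  # smallest (nursing) size
    tank = create_tank(
        store,
        allele_name=cross.line,
        user=cross.user,
        dob=min(r.dob for r in records),
        tank_type=tank_type,
        sex=SexComposition(unsexed=total),
        sire_tuid=cross.sire_tuid,
        dam_tuid=cross.dam_tuid,
        origin_cuid=cross.cuid,
    )
    for rec in records:
        rec.state = "graduated"
        rec.graduated_count = graduated_counts[rec.nuid]
        rec.successor_tuid = tank.tuid
    return tank


# ---------------------------------------------------------------------------
# Harvests
# ---------------------------------------------------------------------------


def create_harvest(
    store: "ColonyStore",
    source: str,
    quantity: int,
    date: Optional[dt.date] = None,
    treatment: str = "",
    age_at_collection: str = "",
) -> Harvest:
    """Harvest embryos from a cross (CUID) or adults from a tank (TUID)."""
    if quantity < 1:
        raise DomainError("harvest quantity must be positive")
    sid = Identifier.parse(source)
    if sid.prefix == "C":
        user = store.cross(source).user
    elif sid.prefix == "T":
        user = store.tank(source).user
    else:
        raise DomainError(
            f"harvest source must be a cross or tank identifier, got {source!r}"
        )
    huid = next_uid(store.registry, "H").rendered
    harvest = Harvest(
        huid=huid,
        source=source,
        date=date or store.clock.today(),
        quantity=quantity,
        treatment=treatment,
        age_at_collection=age_at_collection,
        user=user,
    )
    store.harvests[huid] = harvest
    return harvest


def create_resources(
    store: "ColonyStore", huid: str, group_sizes: Sequence[int], conditions: Sequence[str] = ()
) -> list[HarvestResource]:
    """Split a harvest into sub-indexed resource groups (H0001-1, ...)."""
    harvest = store.harvest(huid)
    if any(s < 1 for s in group_sizes):
        raise DomainError("resource group sizes must be positive")
    if harvest.allocated + sum(group_sizes) > harvest.quantity:
        raise DomainError(
            f"exceeds harvest quantity: {harvest.allocated} already allocated "
            f"+ {sum(group_sizes)} requested > {harvest.quantity} collected"
        )
    hid = Identifier.parse(huid)
    created = []
    next_sub = len(harvest.resources) + 1
    for i, size in enumerate(group_sizes):
        sub = next_sub + i
        rid = Identifier(hid.prefix, hid.serial, sub).rendered
        res = HarvestResource(
            resource_id=rid,
            sub_index=sub,
            group_size=size,
            condition=conditions[i] if i < len(conditions) else "",
        )
        harvest.resources.append(res)
        created.append(res)
    return created


# ---------------------------------------------------------------------------
# Mortality and follow-up
# ---------------------------------------------------------------------------

#: Order in which sex-ledger buckets absorb reported deaths.
_DEATH_ORDER = ("unsexed", "males", "females")


def report_dead(
    store: "ColonyStore",
    tuid: str,
    n_dead: int,
    kind: MortalityKind | str,
    cause: str,
    symptom: str = "",
    date: Optional[dt.date] = None,
    notes: str = "",
) -> MortalityReport:
    """Record found-dead or euthanized fish against a tank's census.

    The tank's fish count is decremented; a tank that reaches zero fish
    is automatically retired and removed from its rack.
    """
    kind = MortalityKind(kind)
    if n_dead < 1:
        raise DomainError("number of dead fish must be positive")
    tank = store.tank(tuid)
    if tank.state != LifecycleState.ACTIVE:
        raise DomainError(f"tank {tuid} is {tank.state.value}")
    if n_dead > tank.fish_count:
        raise DomainError(
            f"count exceeds census: {n_dead} dead > {tank.fish_count} in tank {tuid}"
        )
    report = MortalityReport(
        tank=tuid,
        date=date or store.clock.today(),
        n_dead=n_dead,
        kind=kind,
        cause=cause,
        symptom=symptom,
        notes=notes,
        facility_name=tank.facility_name,
        room=tank.location.room if tank.location else None,
        rack_index=tank.location.rack_index if tank.location else None,
    )
    # drain the sex ledger deterministically: unsexed, then males, then females
    remaining = n_dead
    buckets = {
        "males": tank.sex.males,
        "females": tank.sex.females,
        "unsexed": tank.sex.unsexed,
    }
    for key in _DEATH_ORDER:
        take = min(buckets[key], remaining)
        buckets[key] -= take
        remaining -= take
    tank.sex = SexComposition(**buckets)
    tank.fish_count -= n_dead
    store.mortality_reports.append(report)
    if tank.fish_count == 0:
        retire_tank(store, tuid, LifecycleState.RETIRED)
    return report


def add_follow_up(
    store: "ColonyStore", tuid: str, note: str, date: Optional[dt.date] = None
) -> FollowUpReport:
    """Flag a tank for attention (sick fish, baffle change, etc.)."""
    store.tank(tuid)  # referential integrity
    report = FollowUpReport(
        tank=tuid, date=date or store.clock.today(), note=note
    )
    store.follow_ups.append(report)
    return report


# ---------------------------------------------------------------------------
# Calendar
# ---------------------------------------------------------------------------


def add_event(
    store: "ColonyStore",
    title: str,
    date: dt.date,
    facility: Optional[str] = None,
    room: Optional[str] = None,
    recipients: Sequence[str] = (),
) -> CalendarEvent:
    event = CalendarEvent(
        title=title,
        date=date,
        facility=facility,
        room=room,
        recipients=list(recipients),
    )
    store.events.append(event)
    return event


def _event_recipients(store: "ColonyStore", event: CalendarEvent) -> list[str]:
    """Event recipients plus the administrators of the tank's current room."""
    recipients = list(event.recipients)
    if event.origin == "turnover_auto" and event.source_id in store.tanks:
        tank = store.tanks[event.source_id]
        if tank.location is not None and tank.facility_name:
            room = store.room(tank.facility_name, tank.location.room)
            for admin in room.administrators:
                if admin not in recipients:
                    recipients.append(admin)
    return recipients


def due_reminders(
    store: "ColonyStore",
    on: Optional[dt.date] = None,
    facility: Optional[str] = None,
) -> list[CalendarEvent]:
    """All unacknowledged events due on or before *on*.

    Each due event is routed to the store's notification sink (a log by
    default; swap in an email gateway by assigning
    ``store.notification_sink``).
    """
    on = on or store.clock.today()
    due = [
        e
        for e in store.events
        if not e.acknowledged
        and e.date <= on
        and (facility is None or e.facility in (None, facility))
    ]
    for event in due:
        store.notification_sink(event, _event_recipients(store, event))
    return due


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class PedigreeNode:
    """A node in the ancestor tree; tank and cross generations alternate."""

    id: str
    kind: str  # tank | cross | nursery | harvest
    parents: list["PedigreeNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for p in self.parents:
            yield from p.walk()


def pedigree(store: "ColonyStore", record_id: str, depth: int = 3) -> PedigreeNode:
    """Ancestor tree of a tank, nursery record, or harvest.

    *depth* counts tank generations above the record: depth 1 stops at the
    parents, depth 2 includes grandparents, and so on. Cycles cannot occur
    because parents always predate their children.
    """
    rid = Identifier.parse(record_id)
    if rid.prefix == "T":
        tank = store.tank(record_id)
        return _tank_node(store, tank.tuid, depth)
    if rid.prefix == "N":
        rec = store.nursery_record(record_id)
        node = PedigreeNode(rec.nuid, "nursery")
        node.parents.append(_cross_node(store, rec.cuid, depth))
        return node
    if rid.prefix == "H":
        harvest = store.harvest(record_id)
        node = PedigreeNode(harvest.huid, "harvest")
        src = Identifier.parse(harvest.source)
        if src.prefix == "C":
            node.parents.append(_cross_node(store, harvest.source, depth))
        else:
            node.parents.append(_tank_node(store, harvest.source, depth))
        return node
    raise DomainError(f"no pedigree for identifier {record_id!r}")


def _tank_node(store: "ColonyStore", tuid: str, depth: int) -> PedigreeNode:
    node = PedigreeNode(tuid, "tank")
    if depth < 1:
        return node
    tank = store.tank(tuid)
    if tank.origin_cuid is not None:
        node.parents.append(_cross_node(store, tank.origin_cuid, depth))
    else:
        for parent in (tank.sire_tuid, tank.dam_tuid):
            if parent is not None:
                node.parents.append(_tank_node(store, parent, depth - 1))
    return node


def _cross_node(store: "ColonyStore", cuid: str, depth: int) -> PedigreeNode:
    cross = store.cross(cuid)
    node = PedigreeNode(cuid, "cross")
    if depth >= 1:
        node.parents.append(_tank_node(store, cross.sire_tuid, depth - 1))
        node.parents.append(_tank_node(store, cross.dam_tuid, depth - 1))
    return node
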