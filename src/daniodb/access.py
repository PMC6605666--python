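"""Lab-scoped record visibility and deletion rules.

Every husbandry record belongs to a lab (through its owning user or its
parent record). Ordinary lab users see and modify only their own lab's
records; facility administrators see everything. Fish lines are the one
facility-wide kind: every lab can view them (they are the shared allele
vocabulary) and nobody — not even their owners — may delete them.

Authentication is out of scope: these functions answer authorization for
an already-identified principal.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

from .core import DomainError

if TYPE_CHECKING:  # pragma: no cover
    from .store import ColonyStore

__all__ = [
    "Lab",
    "User",
    "Role",
    "Action",
    "Scope",
    "PermissionRule",
    "RULE_TABLE",
    "add_lab",
    "add_user",
    "can",
    "visible_records",
    "record_lab",
    "export_rule_table",
]


@dataclass
class Lab:
    name: str
    pi: str = ""
    institution: str = ""
    contact: str = ""
    iacuc_protocol: str = ""
    iacuc_expiry: Optional[dt.date] = None


class Role(str, enum.Enum):
    ADMIN = "admin"
    LAB_USER = "lab_user"


@dataclass
class User:
    name: str
    lab: str
    email: str = ""
    phone: str = ""
    active: bool = True
    role: Role = Role.LAB_USER


class Action(str, enum.Enum):
    VIEW = "view"
    MODIFY = "modify"
    DELETE = "delete"


class Scope(str, enum.Enum):
    ALL = "all"
    OWN_LAB = "own_lab"
    NONE = "none"


@dataclass(frozen=True)
class PermissionRule:
    record_kind: str
    action: Action
    scope: Scope


def _rules() -> dict[tuple[str, Action], Scope]:
    """The shipped rule table.

    Lines are viewable by all and deletable by none; every other record
    kind is visible, modifiable and deletable only within the owning lab.
    Modify scope follows view scope (cross-lab records are locked).
    """
    table: dict[tuple[str, Action], Scope] = {
        ("line", Action.VIEW): Scope.ALL,
        ("line", Action.MODIFY): Scope.ALL,
        ("line", Action.DELETE): Scope.NONE,
    }
    lab_scoped = (
        "tank",
        "cross",
        "harvest",
        "harvest_resource",
        "nursery",
        "mortality_report",
        "event",
        "user",
        "lab",
    )
    for kind in lab_scoped:
        for action in Action:
            table[(kind, action)] = Scope.OWN_LAB
    return table


RULE_TABLE = _rules()


def add_lab(store: "ColonyStore", name: str, **fields) -> Lab:
    if not name:
        raise DomainError("lab name must be nonempty")
    if name in store.labs:
        raise DomainError(f"lab {name!r} already exists")
    lab = Lab(name=name, **fields)
    store.labs[name] = lab
    return lab


def add_user(store: "ColonyStore", name: str, lab: str, **fields) -> User:
    if name in store.users:
        raise DomainError(f"user {name!r} already exists")
    if lab not in store.labs:
        raise DomainError(f"unknown lab {lab!r}")
    user = User(name=name, lab=lab, **fields)
    store.users[name] = user
    return user


def record_lab(store: "ColonyStore", kind: str, record) -> Optional[str]:
    """Resolve the lab that owns *record* (None if unowned)."""
    if kind == "lab":
        return record.name
    if kind == "user":
        return record.lab
    if kind in ("tank", "cross", "harvest"):
        return store.users[record.user].lab if record.user in store.users else None
    if kind == "nursery":
        return record_lab(store, "cross", store.cross(record.cuid))
    if kind == "mortality_report":
        tank = store.tanks.get(record.tank)
        return record_lab(store, "tank", tank) if tank else None
    if kind == "event":
        for name in record.recipients:
            if name in store.users:
                return store.users[name].lab
        return None
    if kind == "line":
        return None  # facility-wide vocabulary
    raise DomainError(f"unscoped kind: {kind!r}")


def can(store: "ColonyStore", user: "User | str", action: Action | str, kind: str, record) -> bool:
    """Authorization predicate: may *user* perform *action* on *record*?

    Administrators may do anything. Unknown record kinds are denied.
    """
    if isinstance(user, str):
        user = store.user(user)
    action = Action(action)
    if user.role == Role.ADMIN:
        return True
    rule = RULE_TABLE.get((kind, action))
    if rule is None:
        raise DomainError(f"unscoped kind: {kind!r}")
    if rule is Scope.ALL:
        return True
    if rule is Scope.NONE:
        return False
    return record_lab(store, kind, record) == user.lab


_COLLECTIONS = {
    "line": lambda s: list(s.lines.values()),
    "tank": lambda s: list(s.tanks.values()),
    "cross": lambda s: list(s.crosses.values()),
    "nursery": lambda s: list(s.nursery.values()),
    "harvest": lambda s: list(s.harvests.values()),
    "mortality_report": lambda s: list(s.mortality_reports),
    "event": lambda s: list(s.events),
    "user": lambda s: list(s.users.values()),
    "lab": lambda s: list(s.labs.values()),
}


def visible_records(store: "ColonyStore", user: "User | str", kind: str) -> list:
    """Records of *kind* the user may view; admins see everything."""
    if kind not in _COLLECTIONS:
        raise DomainError(f"unscoped kind: {kind!r}")
    records = _COLLECTIONS[kind](store)
    if isinstance(user, str):
        user = store.user(user)
    return [r for r in records if can(store, user, Action.VIEW, kind, r)]


def export_rule_table() -> str:
    """Render the rule table as an auditable plain-text document."""
    lines = ["record_kind\taction\tscope"]
    for (kind, action), scope in sorted(
        RULE_TABLE.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        lines.append(f"{kind}\t{action.value}\t{scope.value}")
    return "\n".join(lines) + "\n"
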