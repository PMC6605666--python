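import datetime as dt

import pytest
from hypothesis import settings

import daniodb as d

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

#: Frozen "today" used by every fixture clock.
TODAY = dt.date(2026, 6, 1)


@pytest.fixture
def store():
    """A small two-lab colony with one facility, one room, three racks."""
    s = d.ColonyStore(clock=d.Clock.fixed(TODAY))
    d.add_lab(s, "Wythe", pi="J. Wythe", iacuc_protocol="AN-1001")
    d.add_lab(s, "Martin", pi="T. Martin", iacuc_protocol="AN-1002")
    d.add_user(s, "alice", "Wythe", email="alice@example.org")
    d.add_user(s, "bob", "Martin", email="bob@example.org")
    d.add_user(s, "tech", "Wythe", role=d.Role.ADMIN)
    d.configure_facility(
        s,
        "BCM-Main",
        [
            d.TankTypeSpec("0.8L", 1),
            d.TankTypeSpec("2.8L", 1),
            d.TankTypeSpec("5L", 2),
        ],
    )
    d.add_room(s, "BCM-Main", "T032")
    s.room("BCM-Main", "T032").administrators.append("tech")
    for _ in range(3):
        d.add_rack(
            s, "BCM-Main", "T032", d.RackLayout.custom([(10, 1), (10, 1), (20, 1)])
        )
    d.register_line(s, "Tg1", "alleleA")
    d.register_line(s, "mn2", "alleleB")
    return s


def make_tank(
    store,
    allele="alleleA",
    user="alice",
    age_days=100,
    males=3,
    females=3,
    unsexed=0,
    tank_type="2.8L",
):
    dob = store.clock.today() - dt.timedelta(days=age_days)
    return d.create_tank(
        store, allele, user, dob, tank_type, d.SexComposition(males, females, unsexed)
    )


@pytest.fixture(scope="session")
def demo():
    """The seeded 50-tank demo colony used by conservation checks."""
    return d.generate_demo_colony(seed=1)
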