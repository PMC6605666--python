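import datetime as dt

import pytest

import daniodb as d
from daniodb.core import DomainError, LifecycleState, SexComposition, StatusColor
from daniodb.facility import Position
from daniodb.lifecycle import CrossType, MortalityKind, scheduled_graduation_date

from conftest import TODAY, make_tank


class TestLines:
    def test_first_line_gets_l0001(self):
        s = d.ColonyStore(clock=d.Clock.fixed(TODAY))
        line = d.register_line(s, "Tg1", "alleleA")
        assert line.luid == "L0001"

    def test_duplicate_locus_allele_rejected(self, store):
        with pytest.raises(DomainError, match="already registered"):
            d.register_line(store, "Tg1", "alleleA")

    def test_allele_enters_vocabulary_used_by_create_tank(self, store):
        with pytest.raises(DomainError, match="unknown allele"):
            make_tank(store, allele="alleleC")
        d.register_line(store, "sa9", "alleleC")
        assert make_tank(store, allele="alleleC").line == "alleleC"

    def test_empty_allele_rejected(self, store):
        with pytest.raises(DomainError):
            d.register_line(store, "Tg9", "")


class TestTanks:
    def test_turnover_is_one_year_after_dob(self, store):
        dob = dt.date(2026, 1, 1)
        tank = d.create_tank(
            store, "alleleA", "alice", dob, "2.8L", SexComposition(2, 2, 0)
        )
        assert tank.turnover == dt.date(2027, 1, 1)

    def test_future_dob_rejected(self, store):
        with pytest.raises(DomainError, match="future"):
            d.create_tank(
                store, "alleleA", "alice", TODAY + dt.timedelta(1), "2.8L",
                SexComposition(1, 1, 0),
            )

    def test_unknown_tank_type_rejected(self, store):
        with pytest.raises(DomainError, match="catalog"):
            make_tank(store, tank_type="50L")

    def test_inactive_user_cannot_own_records(self, store):
        store.users["alice"].active = False
        with pytest.raises(DomainError, match="inactive"):
            make_tank(store)

    def test_parent_edges_stored_and_retrievable(self, store):
        sire, dam = make_tank(store), make_tank(store)
        child = d.create_tank(
            store, "alleleA", "alice", TODAY, "2.8L", SexComposition(0, 0, 5),
            sire_tuid=sire.tuid, dam_tuid=dam.tuid,
        )
        tree = d.pedigree(store, child.tuid)
        assert {n.id for n in tree.walk()} == {child.tuid, sire.tuid, dam.tuid}

    def test_retire_is_terminal(self, store):
        tank = make_tank(store)
        d.retire_tank(store, tank.tuid)
        with pytest.raises(DomainError, match="already"):
            d.retire_tank(store, tank.tuid)


class TestCrosses:
    def test_trio_units_are_one_male_two_females(self, store):
        sire, dam = make_tank(store), make_tank(store)
        cross = d.set_up_cross(store, sire.tuid, dam.tuid, "trio")
        assert [(u.males, u.females) for u in cross.units] == [(1, 2)]

    def test_eight_pairs(self, store):
        sire = make_tank(store, males=8, females=0)
        dam = make_tank(store, males=0, females=8)
        cross = d.set_up_cross(store, sire.tuid, dam.tuid, "pair", n_units=8)
        assert len(cross.units) == 8
        assert all((u.males, u.females) == (1, 1) for u in cross.units)

    def test_bulk_counts_user_specified(self, store):
        sire = make_tank(store, males=6, females=0)
        dam = make_tank(store, males=0, females=6)
        cross = d.set_up_cross(
            store, sire.tuid, dam.tuid, "bulk", bulk_counts=(5, 5)
        )
        assert (cross.units[0].males, cross.units[0].females) == (5, 5)

    def test_sire_without_males_rejected(self, store):
        sire = make_tank(store, males=0, females=4)
        dam = make_tank(store)
        with pytest.raises(DomainError, match="sex composition insufficient"):
            d.set_up_cross(store, sire.tuid, dam.tuid, "pair")

    def test_inactive_parent_rejected(self, store):
        sire, dam = make_tank(store), make_tank(store)
        d.retire_tank(store, sire.tuid)
        with pytest.raises(DomainError, match="inactive parent"):
            d.set_up_cross(store, sire.tuid, dam.tuid, "pair")

    def test_retire_cross_goes_gray_and_once_only(self, store):
        sire, dam = make_tank(store), make_tank(store)
        cross = d.set_up_cross(store, sire.tuid, dam.tuid, "pair")
        assert d.cross_color(cross.start, cross.retired, TODAY) == d.CrossColor.GREEN
        d.retire_cross(store, cross.cuid, success=True)
        assert d.cross_color(cross.start, cross.retired, TODAY) == d.CrossColor.GRAY
        with pytest.raises(DomainError, match="already retired"):
            d.retire_cross(store, cross.cuid)

    def test_retired_cross_excluded_from_active_listing(self, store):
        sire, dam = make_tank(store), make_tank(store)
        c1 = d.set_up_cross(store, sire.tuid, dam.tuid, "pair")
        c2 = d.set_up_cross(store, sire.tuid, dam.tuid, "pair")
        d.retire_cross(store, c1.cuid)
        active = [c for c in store.crosses.values() if not c.retired]
        assert [c.cuid for c in active] == [c2.cuid]


class TestNursery:
    def _cross(self, store):
        sire, dam = make_tank(store), make_tank(store)
        return d.set_up_cross(store, sire.tuid, dam.tuid, "pair")

    def test_raise_fry_issues_sequential_nuids(self, store):
        cross = self._cross(store)
        records = d.raise_fry(store, cross.cuid, fry_per_dish=30, n_dishes=2)
        assert [r.nuid for r in records] == ["N0001", "N0002"]
        assert all(r.initial_fry == 30 for r in records)

    def test_zero_fry_rejected(self, store):
        cross = self._cross(store)
        with pytest.raises(DomainError):
            d.raise_fry(store, cross.cuid, fry_per_dish=0)

    def test_graduation_date_is_day_five(self, store):
        cross = self._cross(store)
        rec = d.raise_fry(
            store, cross.cuid, 30, dob=dt.date(2026, 3, 1)
        )[0]
        assert scheduled_graduation_date(rec) == dt.date(2026, 3, 6)
        due = d.due_reminders(store, on=dt.date(2026, 3, 6))
        assert any(e.source_id == rec.nuid for e in due)

    def test_graduate_sums_survivors_and_links_pedigree(self, store):
        cross = self._cross(store)
        d.raise_fry(store, cross.cuid, fry_per_dish=30, n_dishes=2)
        tank = d.graduate(store, {"N0001": 22, "N0002": 25})
        assert tank.fish_count == 47
        assert (tank.sire_tuid, tank.dam_tuid) == (cross.sire_tuid, cross.dam_tuid)
        assert tank.origin_cuid == cross.cuid
        n1 = store.nursery["N0001"]
        assert n1.state == "graduated" and n1.graduated_count == 22
        assert n1.successor_tuid == tank.tuid
        assert n1.graduated_count / n1.initial_fry == pytest.approx(22 / 30)

    def test_graduate_rejects_mixed_crosses(self, store):
        c1, c2 = self._cross(store), self._cross(store)
        d.raise_fry(store, c1.cuid, 30)
        d.raise_fry(store, c2.cuid, 30)
        with pytest.raises(DomainError, match="genotype mismatch"):
            d.graduate(store, {"N0001": 10, "N0002": 10})

    def test_graduate_twice_rejected(self, store):
        cross = self._cross(store)
        d.raise_fry(store, cross.cuid, 30)
        d.graduate(store, {"N0001": 20})
        with pytest.raises(DomainError, match="already"):
            d.graduate(store, {"N0001": 20})

    def test_survivors_cannot_exceed_initial(self, store):
        cross = self._cross(store)
        d.raise_fry(store, cross.cuid, 30)
        with pytest.raises(DomainError):
            d.graduate(store, {"N0001": 31})


class TestHarvests:
    def test_embryo_harvest_from_cross(self, store):
        sire, dam = make_tank(store), make_tank(store)
        cross = d.set_up_cross(store, sire.tuid, dam.tuid, "pair")
        harvest = d.create_harvest(store, cross.cuid, quantity=50)
        assert harvest.huid == "H0001"

    def test_adult_harvest_from_tank(self, store):
        tank = make_tank(store)
        harvest = d.create_harvest(store, tank.tuid, quantity=3)
        assert harvest.source == tank.tuid

    def test_zero_quantity_rejected(self, store):
        tank = make_tank(store)
        with pytest.raises(DomainError):
            d.create_harvest(store, tank.tuid, quantity=0)

    def test_split_fifty_into_two_groups_of_25(self, store):
        tank = make_tank(store)
        harvest = d.create_harvest(store, tank.tuid, quantity=50)
        resources = d.create_resources(store, harvest.huid, [25, 25])
        assert [r.resource_id for r in resources] == [
            f"{harvest.huid}-1",
            f"{harvest.huid}-2",
        ]
        assert [r.group_size for r in resources] == [25, 25]

    def test_oversubscription_rejected(self, store):
        tank = make_tank(store)
        harvest = d.create_harvest(store, tank.tuid, quantity=10)
        with pytest.raises(DomainError, match="exceeds harvest quantity"):
            d.create_resources(store, harvest.huid, [11])

    def test_remainder_may_stay_unallocated(self, store):
        tank = make_tank(store)
        harvest = d.create_harvest(store, tank.tuid, quantity=7)
        d.create_resources(store, harvest.huid, [3, 2])
        assert harvest.allocated == 5  # 2 embryos remain on the harvest
        # later split may claim the remainder but no more
        d.create_resources(store, harvest.huid, [2])
        with pytest.raises(DomainError):
            d.create_resources(store, harvest.huid, [1])

    def test_sub_indices_stay_consecutive_across_calls(self, store):
        tank = make_tank(store)
        harvest = d.create_harvest(store, tank.tuid, quantity=10)
        d.create_resources(store, harvest.huid, [2, 2])
        more = d.create_resources(store, harvest.huid, [2])
        assert more[0].resource_id == f"{harvest.huid}-3"


class TestMortality:
    def test_report_decrements_census(self, store):
        tank = make_tank(store, males=4, females=4, unsexed=2)
        d.report_dead(store, tank.tuid, 2, "found_dead", "fungal infection")
        assert tank.fish_count == 8

    def test_report_exceeding_census_rejected(self, store):
        tank = make_tank(store, males=4, females=4, unsexed=0)
        with pytest.raises(DomainError, match="count exceeds census"):
            d.report_dead(store, tank.tuid, 9, "found_dead", "unknown")

    def test_emptied_tank_auto_retires_black_and_unplaced(self, store):
        tank = make_tank(store, males=2, females=1, unsexed=0)
        d.place_tank(store, tank.tuid, Position("T032", 1, "A", 1))
        d.report_dead(store, tank.tuid, 3, "euthanized", "old age")
        assert tank.fish_count == 0
        assert tank.state == LifecycleState.RETIRED
        assert d.tank_status(tank.dob, tank.state, TODAY) == StatusColor.BLACK
        assert tank.location is None

    def test_sex_ledger_never_negative_and_sums_to_census(self, store):
        tank = make_tank(store, males=3, females=2, unsexed=1)
        for n in (1, 2, 2):
            d.report_dead(store, tank.tuid, n, "found_dead", "unknown")
        assert tank.sex.total == tank.fish_count == 1
        assert min(tank.sex.males, tank.sex.females, tank.sex.unsexed) >= 0

    def test_census_conservation_over_random_reports(self, store):
        import random

        rng = random.Random(7)
        tank = make_tank(store, males=10, females=10, unsexed=10)
        initial, reported = tank.fish_count, 0
        while tank.fish_count > 0:
            n = rng.randint(1, tank.fish_count)
            d.report_dead(store, tank.tuid, n, "found_dead", "unknown")
            reported += n
        assert initial == tank.fish_count + sum(
            r.n_dead for r in store.mortality_reports
        )
        assert reported == initial


class TestPedigree:
    def test_three_generation_depth_limit(self, store):
        gp_sire, gp_dam = make_tank(store, age_days=400), make_tank(store, age_days=400)
        c1 = d.set_up_cross(store, gp_sire.tuid, gp_dam.tuid, "pair")
        d.raise_fry(store, c1.cuid, 30, dob=TODAY - dt.timedelta(days=200))
        parent = d.graduate(store, {"N0001": 20})
        parent.sex = SexComposition(5, 5, 10)  # sexed at maturity
        parent2 = make_tank(store, age_days=150)
        c2 = d.set_up_cross(store, parent.tuid, parent2.tuid, "pair")
        d.raise_fry(store, c2.cuid, 20, dob=TODAY - dt.timedelta(days=10))
        child = d.graduate(store, {"N0002": 15})

        ids_depth2 = {n.id for n in d.pedigree(store, child.tuid, depth=2).walk()}
        assert {gp_sire.tuid, gp_dam.tuid} <= ids_depth2  # grandparents included
        ids_depth1 = {n.id for n in d.pedigree(store, child.tuid, depth=1).walk()}
        assert gp_sire.tuid not in ids_depth1
        assert {parent.tuid, parent2.tuid} <= ids_depth1

    def test_founder_tank_is_leaf(self, store):
        tank = make_tank(store)
        tree = d.pedigree(store, tank.tuid)
        assert tree.parents == []

    def test_harvest_pedigree_reaches_cross_parents(self, store):
        sire, dam = make_tank(store), make_tank(store)
        cross = d.set_up_cross(store, sire.tuid, dam.tuid, "pair")
        harvest = d.create_harvest(store, cross.cuid, quantity=50)
        ids = {n.id for n in d.pedigree(store, harvest.huid).walk()}
        assert {harvest.huid, cross.cuid, sire.tuid, dam.tuid} <= ids

    def test_unknown_id_rejected(self, store):
        with pytest.raises(DomainError):
            d.pedigree(store, "T9999")


class TestCalendar:
    def test_turnover_reminder_fires_on_turnover_date(self, store):
        tank = make_tank(store, age_days=30)
        assert d.due_reminders(store, on=TODAY) == []
        due = d.due_reminders(store, on=tank.turnover)
        assert [e.source_id for e in due] == [tank.tuid]
        assert due[0].origin == "turnover_auto"

    def test_empty_calendar_is_empty(self):
        s = d.ColonyStore(clock=d.Clock.fixed(TODAY))
        assert d.due_reminders(s) == []

    def test_recipients_include_owner_and_room_admins(self, store):
        tank = make_tank(store)
        d.place_tank(store, tank.tuid, Position("T032", 1, "A", 1))
        delivered = []
        store.notification_sink = lambda event, recipients: delivered.append(
            (event.title, tuple(recipients))
        )
        d.due_reminders(store, on=tank.turnover)
        assert delivered and delivered[0][1] == ("alice", "tech")

    def test_manual_event_and_acknowledgement(self, store):
        event = d.add_event(
            store, "alternate food", TODAY, facility="BCM-Main", recipients=["alice"]
        )
        assert event in d.due_reminders(store, on=TODAY)
        event.acknowledged = True
        assert event not in d.due_reminders(store, on=TODAY)
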