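# daniodb

Relational colony management for zebrafish (*Danio rerio*) facilities:
a Python library and CLI covering the full husbandry record chain —
fish lines, tanks, crosses, nursery fry, harvests — plus a virtual
facility of rooms and racks, lab-scoped access control, and
census/vitality/mortality/water-quality reporting.

Zebrafish husbandry records are still widely kept in notebooks and
spreadsheets, which cannot enforce allele nomenclature, cannot express
pedigrees, and cannot answer facility-level questions ("how many tanks
does lab X have on the system?", "what killed fish in room T032 last
month?"). `daniodb` models the colony relationally and issues every
record a prefixed serial identifier that links the chain together.

## The data model

Each record kind has a zero-padded serial identifier issued by a
per-prefix registry:

| prefix | record | example |
|---|---|---|
| `L` | fish line (allele) | `L0001` |
| `T` | tank | `T0370` |
| `C` | cross (mating) | `C0831` |
| `N` | nursery dish of fry | `N0002` |
| `H` | harvest; resources are sub-indexed | `H0001-2` |

The reproduction chain *tank → cross → nursery → tank* is the pedigree:
a cross records its sire and dam TUIDs, fry raised from it get NUIDs,
and graduating dishes (at day 5) creates a new tank whose parents are
the cross's parents. Harvests pull embryos from a cross or adults from
a tank and can be split into sub-indexed experimental resources.

Tanks are colour-coded as a pure function of age and lifecycle state:
**white** under 14 days, **yellow** 14–89 days, **green** 90–364 days
(mating age), **red** from 365 days (due for turnover, scheduled one
calendar year after the date of birth), **black** once retired or
euthanized. Crosses are **green** under one day old, **red** after, and
**gray** once retired.

Racks are row-structured grids in which a tank of width *w* spaces
claims *w* contiguous columns; occupancy is exclusive, and
`locate_tank` inverts `place_tank`. Every identifier doubles as a
Code 39 barcode payload for tank, cross, petri-dish and rack-coordinate
labels.

## Worked example

```python
import datetime as dt
import daniodb as d

store = d.ColonyStore(clock=d.Clock.fixed(dt.date(2026, 6, 1)))
d.add_lab(store, "Wythe", pi="J. Wythe", iacuc_protocol="AN-1001")
d.add_user(store, "alice", "Wythe")
d.configure_facility(store, "BCM-Main", [
    d.TankTypeSpec("0.8L", 1), d.TankTypeSpec("2.8L", 1), d.TankTypeSpec("5L", 2),
])
d.add_room(store, "BCM-Main", "T032")
for _ in range(3):
    d.add_rack(store, "BCM-Main", "T032",
               d.RackLayout.custom([(10, 1), (10, 1), (20, 1)]))
d.register_line(store, "Tg1", "kdrl:GFP")

sire = d.create_tank(store, "kdrl:GFP", "alice", dt.date(2025, 9, 1),
                     "2.8L", d.SexComposition(males=4, females=0))
dam = d.create_tank(store, "kdrl:GFP", "alice", dt.date(2025, 9, 1),
                    "2.8L", d.SexComposition(males=0, females=4))
d.place_tank(store, sire.tuid, d.Position("T032", 3, "C", 15))
print(d.locate_tank(store, sire.tuid)[1])

cross = d.set_up_cross(store, sire.tuid, dam.tuid, "trio")
dishes = d.raise_fry(store, cross.cuid, fry_per_dish=30, n_dishes=2)
tank = d.graduate(store, {"N0001": 22, "N0002": 25})
print(tank.tuid, "fish:", tank.fish_count, "parents:", tank.sire_tuid, tank.dam_tuid)

harvest = d.create_harvest(store, cross.cuid, quantity=50,
                           treatment="heat shock", age_at_collection="24 hpf")
print([r.resource_id for r in d.create_resources(store, harvest.huid, [25, 25])])
```

prints

```
BCM-Main / Room T032 / Rack 3 / Row C, position 15
T0003 fish: 47 parents: T0001 T0002
['H0001-1', 'H0001-2']
```

The placed tank is found exactly where it was put; the graduated tank's
47 fish are the summed per-dish survivors (22 + 25) and its pedigree
points at the cross's sire and dam; the 50-embryo harvest splits into
two sub-indexed 25-embryo resources. The trio cross's single mating
unit is one male and two females, and `tank_status` on 2026-06-01
reports the 9-month-old sire as `green` (mating age).

The same workflows are available from the shell:

```sh
daniodb --store colony.db demo --seed 1          # seeded 50-tank demo colony
daniodb --store colony.db tank locate T0001
daniodb --store colony.db report stats --facility MAIN
daniodb --store colony.db report vitality --facility MAIN --period year
daniodb --store colony.db backup backups/        # 7-deep snapshot rotation
```

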