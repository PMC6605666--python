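# Methods

## Model

`daniodb` models a zebrafish facility as a single-writer relational
store. Five record families carry prefixed serial identifiers (L/T/C/N/H
plus sub-indexed harvest resources), issued by a per-prefix registry
whose counters only move forward; an administrator may reset a counter
after deleting records, but never to a value that would collide with a
serial still present in the store. Serials render zero-padded to four
digits, matching the printed form of every identifier in the field
(`T0370`, `H0001-1`), and widen past 9,999 rather than overflowing.

All age-dependent behaviour is a pure function of dates drawn from an
injectable `Clock`, so a census computed for a pinned date is fully
reproducible. Colloquial age classes are fixed to day counts: 2 weeks =
14 days, 3 months = 90 days, 1 year = 365 days. The class boundary is
inclusive for the later class (a tank exactly 14 days old is yellow,
exactly 365 days old red); the sources that describe the colour scheme
disagree on the boundary ("younger than 2 weeks" vs "≤ 2 weeks"), and
the inclusive-later rule makes the classifier total and monotone in
age. Turnover is one *calendar* year after the date of birth (Feb 29 →
Feb 28) rather than a flat 365 days, because turnover is a husbandry
appointment, not an age threshold. Cross colour flips from green to red
at one day: descriptions of the scheme vary between one and two days,
and the stricter bound was kept since its purpose is prompting users to
return fish to the system.

### Rack geometry

A rack is an ordered list of lettered rows; a row with *n* tank slots of
*s* spaces each has capacity *n·s* columns. A column indexes one space;
a tank whose type occupies *w* spaces claims *w* contiguous columns from
its anchor. Exclusivity of these spans is the occupancy invariant,
enforced on placement and movement (moves are atomic: on failure the old
span is untouched). "Position 15" therefore counts spaces, not tank
slots. Vendor rack presets (Tecniplast, Aquaneering, Pentair) ship as an
editable JSON data file with representative placeholder grids — vendors
do not publish one canonical layout, so administrators are expected to
edit the file to match their installation.

### Husbandry workflows

Mating units are fixed by cross type — a pair is (1 male, 1 female), a
trio (1, 2) — and bulk unit composition is caller-specified with a
documented default of (5, 5). Males are debited against the sire tank's
sex ledger and females against the dam tank's when checking feasibility,
but fish are *not* removed from their home tanks during mating: crosses
are labelled out and the fish returned. Fry raised from a cross are
scheduled to graduate at day 5; graduation requires all dishes to share
one cross — the strictest checkable proxy for "same genotype" — and the
new tank inherits line, owner, and the cross's parents.

Mortality reports decrement a tank's census, draining the sex ledger in
a fixed order (unsexed, then males, then females) since the sex of the
dead fish is not recorded. A tank that reaches zero fish is retired
automatically and removed from its rack; manual retirement is also
terminal. Harvest resources are sub-indexed consecutively and may leave
a remainder unallocated on the harvest, but can never oversubscribe the
collected quantity.

### Access control

Authorization is lab-scoped: an ordinary user may view/modify/delete
only records owned by their lab (ownership resolves through the owning
user, or through the parent record for nursery/mortality/harvest
records), administrators may do anything, and fish lines are the one
facility-wide kind — viewable by all labs because they are the shared
allele vocabulary, and deletable by none. The shipped rule table lists
only view and delete scopes explicitly in its source material; modify
was set equal to view ("records locked for modification" cross-lab),
and the kinds whose delete scope was unstated (dead-fish reports,
laboratories) were given the same lab scope as their view rule.
Authentication is out of scope: the API takes an identified principal.

### Reporting

Reports aggregate at facility ⊃ room ⊃ rack scope. Tanks enter a scope
through their rack placement, so retired tanks (which are removed from
racks) drop out of the census histogram — the "black" bin of a scoped
census is therefore zero unless a placed tank is mid-retirement, and
facility totals equal the sum over rooms by construction. Births and
deaths are scoped by a location snapshot taken when the nursery record
or mortality report was created, keeping historical reports stable when
tanks later move or retire. Reporting windows: week = seven daily
buckets ending at the anchor; month = the anchor's calendar month in
Monday-start week buckets; year = twelve calendar months. Buckets are
dense (zero-count buckets are emitted) so exported chart series align.

"Births" counts nursery `initial_fry` only; harvested embryos are
tracked under their HUIDs and are deliberately not double-counted as
births. Mortality pie fractions are weighted by the number of dead fish
per report and each nonempty distribution sums to 1. Water-quality
error bars are the sample standard deviation (0 for a single reading);
readings are validated against the calendar at ingest. Chart exports
are lossless label/value(/error) tables in CSV or JSON; no external
charting service is called.

## Persistence and labels

The store persists to a single-file SQLite database: one table per
record kind, keyed by the record's identifier, with the record payload
as a sorted-key JSON document (nested structure — occupancy spans,
mating units, readings — stays inside the document). Saves are atomic
(write-temp-then-rename) and loads verify referential integrity.
Backups are full snapshots in a rotation that retains the last seven;
the new snapshot is written before any eviction, so a failed snapshot
never costs an existing one.

Code 39 encoding/decoding is implemented from the public symbology
table (43 characters plus the `*` sentinel, nine elements per symbol,
exactly three wide) because barcode round-tripping is a package
invariant and no barcode library is a dependency. Labels are emitted as
structured payloads (fields plus barcode text); physical layout and
printer dialects are out of scope. Notification delivery is a pluggable
sink defaulting to a log — e-mail transport is deliberately not
implemented.

## Demo colony generator

`generate_demo_colony(seed, ...)` builds the fixture colony used by the
test suite and the acceptance script: by default 2 labs (two users each
plus one facility administrator), 6 lines, 10 crosses (about two thirds
retired, with fecundity noted), and 50 placed tanks over a 365-day
horizon ending 2026-06-01 — sizes chosen as a realistic small facility
room that still exercises every record kind. The generator replays the
colony chronologically through the public API (the clock is advanced to
each event's date), so every invariant the API enforces also holds in
the fixture. `n_tanks` counts *placed* tanks including the two tanks
created by graduating fry; founder sex ledgers are drawn with at least
two fish of each sex so any founder can serve as sire or dam; mortality
reports never empty a tank so the placed-tank total stays at `n_tanks`.
Water-quality readings cover all six parameters (conductivity, pH,
temperature, nitrites, nitrates, chlorine) for one rack-month at
realistic set-points with ±5% noise.

What the generator does not emulate: seasonal fecundity drift, clutch
size variation by line, disease outbreaks with correlated mortality,
partial sexing error, or multi-facility stores. Passing tests therefore
demonstrate the bookkeeping invariants (conservation, exclusivity,
round-trips, scoping), not husbandry outcomes of a real facility.

## Numerical and degenerate-input choices

- Distributions are plain count ratios; no smoothing. Empty report sets
  yield empty distributions, never division by zero.
- Sample SD uses n−1; a single reading reports SD 0 by convention.
- Date arithmetic is pure `datetime`; the only irregular case is the
  leap-day turnover mapping.
- Ties in placement never arise: a span either fits and is free, or the
  operation is rejected with the reason ("occupied" / "out of range").
- Degenerate stores (no facility, empty racks, empty calendars) return
  empty results or a named `DomainError`, never partial state; all
  mutating operations validate before mutating.

## Known limitations

- Single-writer, in-memory store; no concurrency control or record
  locking. The persistence layer documents (and tests) a single-writer
  contract only.
- Room administrators are modelled as users with the admin role rather
  than a distinct cross-lab role.
- The rack presets are placeholders, not vendor-verified grids.
- Attachment and gel-image fields store file paths verbatim; images are
  never parsed.
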