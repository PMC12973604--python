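# Methods

This note documents the models and procedures implemented in `sholink`,
the defaults and why they were chosen, what the synthetic data do and do
not emulate, and the numerical conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The linkage procedure

### Finder file

The registry side is reduced to one identifier record per individual
(identifiers from the licensing record where present, otherwise from the
crash driver-level record; `appears_in` tracks which datasets qualify the
person). Three audited filters follow:

1. **Eligibility** — a record in the licensing or crash data, birth year in
   1900–1954 (the cohort age-eligible for Medicare during the claims
   overlap years), and not dead before 2007-01-01. "Died in or before
   2006" is read as `death_date < 2007-01-01`, i.e., calendar-year
   language.
2. **Completeness** — non-missing first name, last name, sex, date of
   birth, state, and ZIP. A missing death date is allowed (most people are
   alive).
3. **Post-65 survival** — death strictly before the 65th birthday
   excludes; dying *on* the birthday retains, because age-based Medicare
   entitlement begins with that month. A Feb-29 birthday rolls to Mar-1.

The filters are pure conjunctions, so final membership is order-invariant;
stage counts are recorded after each step. Records with unparseable dates
go to a rejects report rather than being silently dropped, keeping the
cascade auditable. Each survivor receives a fresh `sho_id` issued in
sorted source-row order.

### Blocking

Candidate pairs are the union of three blocks: (surname Soundex, birth
year), (exact date of birth), and (ZIP, birth year). Any pair agreeing
exactly on all six identifiers agrees on every key, so exact matches are
guaranteed to be generated. No scalable blocking scheme can generate
*every* pair with a nonzero name or age similarity (for instance, a shared
surname with birth years a decade apart appears in no block); the test
suite therefore verifies containment on the guaranteed classes — exact
six-field agreement, and equal canonical surname plus birth year — and
verifies that bulk scoring agrees with the record-by-record comparators on
every generated pair.

### Category comparators

All comparators are symmetric, deterministic, and return
`None < Low < Medium < High`. Names are canonicalized first (case-fold,
diacritic stripping, removal of hyphens/apostrophes/spaces). A missing
field yields `None` for its category; by construction the finder file is
complete on the six fields, so in practice this matters only for death
dates, which are handled inside the age comparator.

* **Name.** Last names equal: High if first names equal; Medium if the
  first-name pair is a nickname hit, has Jaro-Winkler ≥ 0.88, or is within
  one keystroke edit; otherwise Low. Last names unequal: Medium only when
  the last names are within one keystroke edit *and* the first names are
  exactly equal; otherwise None. Two anchors fix the ladder: John/Jon ⇒
  Medium, John/Frank ⇒ Low. The keystroke distance is
  optimal-string-alignment (Damerau) distance — substitution, deletion,
  insertion, or adjacent transposition each cost one — because a
  transposed pair of letters is a single typing error. A nickname hit
  includes two variants of the same canonical name (Betty and Liz both
  resolve to Elizabeth). Thresholds live in `NameRules` and are
  config-overridable.
* **Sex.** High on exact non-missing F/M agreement, else None. The binary
  field admits no useful intermediate levels.
* **Age.** High iff birth dates are exactly equal and death dates are
  compatible (equal, or missing on either side). Medium for a single
  day-or-month discrepancy, or a day/month transposition, with the year
  equal. Low for any other same-year discrepancy or a full date within ±1
  year. None otherwise. A death-date conflict (both present, unequal)
  caps the category at Low. Year errors deliberately rate no better than
  Low: for an age-defined cohort a wrong birth year is a materially worse
  signal than a wrong day or month, which is also why acceptance strategies
  that require High age allow "little room for common errors in birth-date
  components".
* **Residence.** High on state plus full 5-digit ZIP; Medium on state plus
  the 3-digit ZIP prefix (same sectional center — a short-distance move);
  Low on state only; None when states differ or are missing.

### Confidence pattern table

The default first-match-wins table is

| pattern | confidence |
|---|---|
| ≥ 3 categories High | Strong |
| name ≥ Medium and age ≥ Medium | Fair |
| (fallthrough) | Weak |

This is the simplest table that (a) maps all-High to Strong and High-name/
Medium-elsewhere to Fair, (b) guarantees that every Strategy-5 acceptance
is Strong or Fair (checked exhaustively over all 4⁴ quality patterns), and
(c) keeps the strategy counts ordered as observed (every 3-of-4-Highs
acceptance is Strong, hence Strategy 2 ⊆ Strategy 1). The table is part of
the run configuration, so studies that band confidence differently can
swap it without touching code.

### Resolution, crosswalk, reporting

Confidence is assigned before resolution because the resolution ranking
uses it: for each contested registry id or beneficiary id the maximal
candidate under (confidence, count of Highs, name quality, age quality)
is kept, with exact ties broken toward the lexicographically smaller
`bene_id` then `sho_id`. The kept set has unique ids on both sides;
kept pairs that had competition are flagged `one_to_many_resolved`.
Accepted pairs receive sequential opaque BIDs in sorted `sho_id` order, so
the crosswalk is a pure function of the accepted set. All reported
percentages use one rule — numerator/denominator × 100, rounded to two
decimals half away from zero — which reproduces printed cohort percentages
exactly from their printed counts.

## 2. The person-month panel and annual report

License phase intervals are half-open `[start, end)`: the start day is
licensed, the end day is not, so adjacent phases never double-count a day.
The panel holds one row per linked person per month from the window start
through the month of death (the death month generates a row, since annual
cohorts include decedents). A month is fee-for-service covered iff the
beneficiary summary marks it FFS (Parts A+B without a capitated Part C
plan). Crashes are counted by crash date through the crash-level record,
so two drivers in one collision each count the shared crash once. Events
for unlinked individuals, or dated outside the panel's window/death
bounds, are retained in an audit file.

The report-year cohort keeps BIDs aged ≥ 65 at the year start (fixed
reference date for determinism) whose every alive month in the year is FFS
("throughout the year or until death"), requiring at least one alive
month. Ages are measured on December 31 or at death. **Licensed all
year** requires a valid phase on every calendar day of the year — the
strict reading of an annual licensure indicator, as opposed to the panel's
monthly any-day flag; the helper is exposed so the monthly definition can
be substituted.

## 3. The synthetic sources

The generator emulates the two administrative sources at the fidelity the
linkage needs, with a known crosswalk:

* **Population.** `n` persons; sex ≈ 52% female; given names and surnames
  drawn from fixture pools with Zipf-like weights (`w ∝ rank^-s`, s = 0.8
  for given names, 0.9 for surnames) so that common names — and therefore
  confusable people — are realistically common. Birth dates uniform over
  1900–1954. A configurable fraction (`overlap`, default 0.85) appears in
  both sources; the remainder splits evenly between registry-only and
  Medicare-only.
* **Name pools.** The ~160 canonical given names and ~130 surnames are
  pairwise dissimilar (≥ 2 keystroke edits; given names also Jaro-Winkler
  < 0.88 and nickname-unrelated), so on uncorrupted data two distinct
  persons can never reach a Medium name quality. Nickname variants (Jon,
  Bob, Peggy, …) enter only through the error model. A test enforces the
  pool invariant.
* **Mortality.** Constant annual hazard 0.037287 after the 65th birthday,
  chosen so that 1 − e^(−h) ≈ 3.66% of an annual cohort dies in-year,
  plus a 5% lifetime probability of death before 65 (uniform over ages
  20–65) so the pre-65-death filter sees real attrition. Deaths beyond the
  data horizon (end of 2024) are recorded as alive.
* **Identifier errors** (per source record, independently on each side):
  nickname substitution (0.08, when the first name has table variants),
  single-keystroke typo per name field (0.01 — administrative name fields
  are high-quality), one birth-date component altered (0.02; the day and
  month move to a random valid value, the year by ±1–2), day/month swap
  (0.005, when representable), sex miscode (0.005), stale residence
  (0.25 — the registry view reports an earlier residence interval; address
  discordance across sources separated by years of moves is by far the
  most common benign mismatch for a retirement-age cohort), and missing
  field (0.0005 per field, matching the sub-percent incompleteness of
  cleaned registry extracts). With all probabilities zero the source views
  equal the truth, and exact linkage recovers the crosswalk perfectly — a
  tested invariant.
* **Events.** Crash involvements, citations, and suspensions are
  homogeneous Poisson processes over alive days in the window, at default
  rates 0.0247, 0.0213, and 0.010 per person-year (crash and citation
  rates calibrated to a 2019 FFS cohort of older adults). A fraction
  (0.15) of crash involvements pair into two-driver crashes sharing a
  crash id; pairing relabels crashes without adding involvements, so
  per-person rates are unchanged. Crashes are reportable (injury or ≥ $500
  damage) by construction. Crash occurrence is independent of licensure —
  a simplification; see limitations.
* **Licensing.** With probability 0.6314 the full-license phase covers the
  whole window; otherwise it lapses or begins mid-window. Learner phases
  (permit, probationary) sit at ages 17–18.5, decades before the claims
  era, as they do for this cohort. License intervals are administrative
  and may outlast death.
* **Coverage.** Enrollment months run from the 65th-birthday month to the
  death month. The FFS-vs-capitated plan is elected once per calendar
  year with P(FFS) = 0.63 (capitated share ≈ 37%, the 2019 national
  Medicare Advantage share). An annual election keeps the marginal
  monthly FFS probability at the configured value while making
  "FFS throughout the year" a realistically sized cohort — under
  independent months its probability would be 0.63¹² ≈ 0.4%.
* **Chronic conditions.** Each condition is present with its lifetime
  prevalence (cataracts 0.5583, chronic pain/fatigue/fibromyalgia 0.3064,
  glaucoma 0.2398, hearing impairment 0.1493, dementia 0.1212, epilepsy
  0.0245); onset is uniform between age 45 and the earlier of death and
  the window end, so the ever-diagnosed share at the report-year end
  equals the prevalence.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real data: real nickname/typo frequency structure
(the published linkage reports no empirical error distributions, so the
defaults are conventional); household-correlated addresses and surnames;
duplicate registry records for one person (the upstream registry's
internal linkage is assumed done, one registry record per person);
claims-level utilization, costs, or diagnosis codes; geocoded crash
locations; seasonality or age-dependence of event rates; disenrollment
and plan switching within a year; migration into New Jersey. Real-world
precision/recall will differ from the synthetic operating point; the
synthetic results validate the *machinery* (that the strategies implement
their definitions, that resolution is correct, that calibrated rates
propagate through the panel), not the real-data match rate.

## 4. Numerical and procedural conventions

* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; per-person substreams are derived from a
  seeded master, so exports are byte-identical across runs and stable
  under fixed configs.
* Dates are ISO-8601 strings in all interface files; empty string means
  missing; intervals are half-open.
* Percentages: two decimals, half away from zero (`decimal.Decimal`), one
  shared implementation for the strategy report and the cohort summary.
  An empty cohort reports counts 0 and percents 0.00.
* Tie-breaks in resolution are lexicographic on ids; BIDs are issued in
  sorted `sho_id` order. No step depends on dict or file-system order.
* Validation sizes: ground-truth recovery runs at n = 5,000 (zero error)
  and n = 20,000 × 3 seeds (default errors, pooled counts — the strategy
  trade-offs are directional inequalities, and pooling removes per-seed
  Poisson noise in the small false-positive counts); the calibration run
  uses n = 50,000 with the event window restricted to the report year.
  These sizes give the binomial 3-SE bands a few-tenths-of-a-percent
  width while the whole suite stays fast.

## 5. Known limitations

* The original linkage contractor's exact internal rule tables (full
  category-level definitions and the complete confidence pattern list)
  are not public; the defaults here are the simplest tables consistent
  with the published anchors and orderings, and both are
  configuration-overridable. The published 81%/19% Strong/Fair split
  among accepted matches cannot be reproduced without the full pattern
  list and is not targeted.
* Absolute cohort counts from the restricted data are out of reach by
  design; only printed *ratios* are reproduced exactly, and pipeline
  behaviour is validated on synthetic ground truth.
* The updated band-based (1–7) match-quality procedure used by the linkage
  contractor's newer releases is out of scope.
* `p_licensed_full_year` is defined relative to the simulation window, so
  the licensed-all-year share matches the parameter when the window equals
  the report year (as in the calibration run); longer windows dilute it.
* The one-pass greedy resolution is globally consistent (unique ids both
  sides) but is not a maximum-weight bipartite matching; with realistic
  error rates the difference is confined to rare contested clusters.
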