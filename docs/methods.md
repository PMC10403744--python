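# Methods

This note records the models behind `coplink`, the defaults that matter,
the choices made where the design was genuinely open, and what the
synthetic evaluation does and does not demonstrate.

## Problem setting

A regional police force holds an event-level register: one row per
(crime occurrence, offender identity), keyed by an `offender_id` that is
neither stable (one person can be recorded as several identities) nor
shared with the cohort study.  Linkage therefore runs in two stages:
identity matching on personal identifiers (forename, surname, date of
birth, sex, postcode history), then extraction and filtering of the
matched identities' event records.  Only records whose disposal implies
an admission or charge — charges, cautions, offences taken into
consideration (TICs), penalty notices, cannabis warnings, community
resolutions — are in scope; regional records carry no conviction data.

## Synthetic data generator

The generator exists so the whole pipeline can be validated against
known ground truth.  It emulates the error processes a real
cohort-to-police linkage must survive, each behind an explicit rate:

| parameter | default | what it emulates |
|---|---|---|
| `n_cohort` / `n_background` | 2000 / 500 | cohort roster and non-cohort register identities born in the same window (sizes scaled ~1:6 from the real setting to keep runs in seconds) |
| `offending_rate` | 0.14 | share of cohort members with any register identity (≈ the observed linked share) |
| `fragmentation_rate` | 0.01 | offenders recorded under two `offender_id`s (≈ 19/2273) |
| `twin_rate` | 0.02 | twin individuals sharing surname, DoB and address |
| `name_variant_rate` | 0.05 | formal↔short-form names (nickname table) |
| `typo_rate` | 0.02 | single-character substitutions in a name |
| `stale_address_rate` | 0.20 | the register holds a newer address than the study |
| `fake_id_rate` | 0.01 | wholly fake name given to police (true DoB kept) |
| `group_crime_rate` | 0.12 | occurrences with 2–4 offenders sharing one `occurrence_id` (→ ~¼ of records from group crimes) |
| `consent_rate` | 0.86 | participants permitting criminality linkage |
| `in_area_rate` | 0.90 | address spells inside the policing area |
| `era_boundary` | 2015‑09‑01 | recording-system change: before it, TICs and out-of-court disposals appear only as the legacy term "prosecuted" |
| `electronic_start` / `pre_electronic_drop` | 2007‑01‑01 / 1.0 | paper-era records; the survival of pre-electronic records is unquantified in public sources, so the default drops them all (a free parameter) |
| `extraction_date` | 2021‑07‑01 | right-censoring of events |

Dates of birth span 1991‑01‑01..1993‑01‑31.  All randomness flows from
one seed; identical parameters give byte-identical outputs.

Retention emulates the police review code (MoPI): per offender the most
serious (lowest) group across their offences sets the review category;
category‑3 offenders' records are deleted after a ≥6‑year clear period
before extraction, category 1/2 records are retained.  The review is a
single sweep at extraction, not a rolling schedule — public sources give
review periods, not scheduling.

**Deliberate realism choices.**  The forename pool (80 names) and the
surname pool (240 synthetic syllable composites) are culled so no two
pool members are Jaro–Winkler similar (≥ 0.85): accidental name
similarity between distinct synthetic people is then rarer than a
root+suffix construction would make it (and closer to real populations),
so any similarity the matcher sees traces back to a planted corruption.
Co-twins get forenames with distinct initials — nothing constrains twin
forenames, and this keeps the twin-check rule a sufficient screen in
synthetic data (the retain-branch, e.g. JAMIE/JAMES, is unit-tested
directly).  Postcodes come from an invented gazetteer (22 in-area, 10
out-of-area outward codes); no real postcodes appear anywhere.

**What passing tests do not show.**  The generator draws identifiers
independently (no household or neighbourhood structure beyond twins), has
no ethnicity- or deprivation-differential error rates, uniform offence
dates (no age-crime curve), and name pools far smaller than reality.
Perfect precision on synthetic runs therefore demonstrates that the
*rules* behave as specified under the planted error processes, not that
real-data precision would be 1.0 — on real data, review is manual
precisely because score overlap between true and false links cannot be
fully resolved automatically.

## Probabilistic engine defaults

The commercial engine used in practice exposes none of its internals, so
the Fellegi–Sunter stage here is configuration with documented defaults:

* **m-probabilities** (configuration, not estimable from one extract):
  0.95 for forename/surname/DoB, 0.97 for sex, 0.70 for postcode — the
  low postcode m encodes that study-held addresses are expected to go
  stale on true matches.
* **u-probabilities** are estimated from the data as collision
  probabilities Σ_v p_v q_v (cohort × register value frequencies),
  clamped to [1e‑4, 0.6]; an optional EM refinement
  (`probabilistic.em_refine`) is available behind a flag.
* **Comparators**: Jaro–Winkler for names with agreement threshold 0.85
  (standard for short personal names; validated against published
  reference values); component-wise date comparison with 0.85 credit for
  a day/month transposition; postcode agreement requires the *full*
  postcode — an outward part is shared by thousands of households, so
  outward-only agreement is evidence-graded only through the
  deterministic strength variable, not the score.
* **Decision threshold 14**: under the default models, a pair agreeing
  on DoB and sex plus exactly *one* of {forename, surname, postcode}
  scores ≈ 10.5–12.5, while any configuration retaining two such
  agreements scores ≳ 17.  The threshold sits between, so designation as
  a match requires at least two identifier agreements beyond DoB and
  sex.  The known cost: a true pair with a dissimilar nickname *and* a
  stale address (≈ 0.4% of true pairs at default rates) is missed —
  consistent with the fact that real linkages acknowledge missed matches
  from exactly these causes.
* **Blocking** is the union of three keys — full DoB; (DoB year, surname
  initial); (surname, sex).  DoB is uncorrupted in the generator, so
  true-pair retention is 100% (the acceptance script reports it).

## Review and deduplication

Review rules are hard checks on exact (normalised) agreement, not
similarity: the rules read as verification steps, and a reviewer checking
"forename AND full date of birth" compares values, not scores.  The
bottom decile is computed over all probabilistic links (deterministic
matches are exempt), which makes the twin check and the confidence review
commute on disjoint candidate subsets.  Duplicate resolution: a
postcode-supported claim beats unsupported ones for a contested
`offender_id` (best-supported wins if several; all removed if none), and
a participant holding several `offender_id`s keeps them only if the links
have DoB or postcode support — names alone lack distinguishing power.

Ground-truth evaluation restricts the truth table to linkage-permitted
participants: the pipeline never attempts the others by design, so
counting them as misses would measure consent policy, not linkage
accuracy.

## Severity

Severity = base harm score × 1.3^[domestic abuse] × 1.5^[hate] ×
1.05^[drug] × 1.1^[firearm] × 1.3^[safeguarding children].  The uplifts
are defined as cumulative and ordered, but with no intermediate rounding
multiplication is commutative, so the order-invariant reading is adopted
and tested explicitly.  The bundled harm table carries the eight
publicly documented exemplar scores (0.8 intent to supply class A drugs;
1.45 wounding with intent; 2.9 rape; 8 trafficking for exploitation; 10
child pornography; 30 manslaughter; 50 noxious substance in a terrorism
offence; 100 murder) plus invented low-harm offences so all twelve
offence groups are populated; full harm tables are not public, so user
tables are accepted via `HarmTable` (values outside [0.01, 100] are
errors; values in the undocumented 3–8 gap raise a warning, not an
error, because the gap's rationale is unpublished).

## Disclosure control

* **Pseudonymisation**: HMAC‑SHA256 with a per-release salt, truncated
  to 12 hex characters — deterministic within a release (shared
  `occurrence_id`s keep their linking function), irreversible without
  the key.
* **Ages in completed months**: the month counts only once the
  day-of-month is reached.  "In months" has no single convention;
  completed months is the documented choice, tested against a
  calendar-walk oracle.
* **Top-coding** defaults: severity ≥ 10 → "10+", offender count ≥ 5 →
  "5+" (the real cutoffs are not public; these are this package's
  defaults).
* **Missingness threshold** 0.90: fields emptier than this are withheld
  from release — matching the magnitude of the fields withheld in
  practice (alcohol ≈ 98%, substance ≈ 95%, verdict ≈ 93% missing, all
  reproduced by the generator).
* **Suppression**: cells 0 < n < 5 are hidden; complementary suppression
  closes the smallest-loss 2×2 rectangle through any exposed cell
  (zero-count cells are avoided — they hide nothing) and iterates until
  linear-programming interval protection (min = max under row/column
  margins and published cells) certifies no suppressed count is
  recoverable.  A brute-force integer enumeration on small tables
  confirms the certificate in tests.

## Denominator flags

A birthday is in-area when a covering address spell has an in-area
postcode; a birthday covered by no spell is flagged "false + coverage
gap" so "not resident" and "address unknown" stay distinguishable.  A
birthday falling on a spell boundary belongs to the spell ending that
day.  The area predicate is injected (no real geocoding); the default
tests membership of the synthetic gazetteer's in-area outward codes.

## Problem sizes and determinism

The default pipeline runs 2000 cohort × ~780 register identities and
~1000 event rows in a few seconds; the test suite's oracle comparisons
use 200×200 registers for exhaustive pair scoring, ~10⁴ event rows for
the filtering oracle, 4×3 tables for suppression enumeration and 10³
random date pairs for the age oracle.  Every run is reproducible from
its seed; the pipeline manifest records a configuration hash and
stage-by-stage row counts satisfying conservation (candidates in = final
links + ledgered removals).

## Known limitations

Verdict and court-case fields are carried but not analysed (they are
~90% missing at source).  The generator's offence mix and age profile
are not calibrated to any real cohort.  Suppression protects single
tables; it does not reason about releases of multiple overlapping
tables.  The EM refinement estimates binary-agreement mixtures only.
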