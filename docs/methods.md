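# Methods

## The mapping model

`armdb` maps a set of archetypes, templates and EAV mappings to a
relational schema model (`RelationalSchema`) that records tables, typed
columns, clustered/non-clustered indexes, foreign keys, and a provenance
map from `(archetype, node path, field)` to `(table, column)`.  The model
is the unit of testing; DDL is a rendering of it.

**Which archetypes get tables.** Not every archetype is a table: archetypes
used only as single-occurrence slot fillers (identifier/name/details
clusters, annotations, organisations) are embedded where they are used, and
an abstract generalization parent (the plain `lab_test` archetype) holds no
data of its own.  A main table is created for every archetype that has a
template, that is the specialized side of an EAV mapping, or that is the
target of a multiple-occurrence slot of a tabled archetype (computed to a
fixpoint).  On the shipped suite this yields 12 tables from 17 archetypes.

**Basic data types.** The closed registry maps each basic type to typed
fields (text → NVARCHAR, integer/boolean → INTEGER, double → FLOAT);
reference fields (`DvCodedText.definingCode` → `CodePhrase`) expand
recursively, concatenating field names with underscores.  `DvProportion`
canonically stores only its precision; numerator/denominator FLOAT columns
exist behind `MapperConfig.dv_proportion_extended` (default off) because
the canonical mapping does not define them.  `DvDateTime` is stored as text
and the generator emits ISO-8601 renderings, which sort lexicographically,
so range conditions behave.

**Keys, indexes, nullability.** The identification item becomes the unique
clustered key; without one, a generated INTEGER `id` is added, invisible to
archetype paths.  Child tables (multiple-occurrence collections and items)
always use a generated key plus an indexed foreign-key column and an
`ordinal` column preserving repetition order (the mapping needs it for
faithful round-trips).  Query items get single-column non-clustered
indexes; whether propagated columns should instead join composite indexes
with the child's keys is not defined by the method, so independent
single-column indexes are used.  Columns are NOT NULL exactly when the leaf
and all its ancestors have occurrence lower bound 1.

**Naming.** Table names are an rm-class prefix letter (OBSERVATION→O,
INSTRUCTION→I, demographic PERSON→D, CLUSTER→C, otherwise the class
initial) plus the CamelCased concept name, version-stripped because
compatible versions share a table; child tables append the CamelCased group
name.  Column names join the node names along the (slot-expanded) path with
underscores plus the field suffix; a trailing segment equal to the suffix
is not repeated (`id`, not `id_id`).  Names over the limit (default 64) are
truncated and suffixed with a 4-hex-digit digest of the full name —
deterministic and collision-free in practice (tested at 10⁵ random names).
Identical full names abort the mapping rather than being silently merged.
Column naming can be switched to full-path mode (`column_mode="path"`) for
guaranteed uniqueness at the cost of readability.

**Version semantics.** Archetype pairs classify as REVISION (all old nodes
present with identical types; occurrence upper bounds may widen; additions
allowed), SPECIALIZATION (concept name extends the parent's, constraints
equal or stronger), or NEW_VERSION (type changes, removals, a mandatory
item becoming optional, or narrowed occurrences).  Description/ontology
text changes are ignored — they do not affect stored data.  REVISION merges
into the existing table (new leaves as nullable columns, applied to a live
database with ALTER ... ADD COLUMN); SPECIALIZATION always maps standalone;
NEW_VERSION either keeps a table per version (suffix `V<n>`) or, under
MERGE_AND_CONVERT, builds the new definition, copies data under a declared
field mapping (identity or text/integer/float casts — richer conversion
algorithms are out of scope because none is defined), verifies row counts,
drops the old table and takes over its name, all transactionally.  Value
ranges and terminology bindings are not modelled by the dialect, so
range-narrowing incompatibilities are out of classification scope.

## Storage and query semantics

Instances are value trees mirroring the archetype: leaves carry field
dicts, repetitions are ordered lists, single-occurrence slots nest inline,
multiple-occurrence slots nest child instances.  The ARM store writes
single-occurrence leaves into the main row, repetitions into child tables
(with propagated query-item values copied from the parent), and slot
children into their own archetype's table with the foreign key and
unsuppressed propagated values.  Retrieval inverts this; collection order
is preserved by the ordinal, while multiple-occurrence slot children are
normalized by key order (their tables have no ordinal — they are
first-class instances).

Queries are conjunctions of `(path, field, comparator, literal)` conditions
with comparators `=`, `>=`, `<=`, `LIKE` — the forms the clinical workload
uses.  A condition inside a multiple-occurrence group holds if *some*
repetition satisfies it; conditions sharing an explicit label must hold in
the *same* repetition (the shape translation produces); conditions on
different labels of one group bind different repetitions of the same
instance.  Multi-archetype queries intersect per-archetype *subject* sets,
where the subject is the root `patient` item, or the identification item of
a demographic person archetype.  Execution is stepwise — one simple
statement per condition group, key sets intersected in the application —
with a single-statement EXISTS-join strategy behind a flag for comparison.
Numeric literals against text storage compare under SQL CAST semantics
(leading-numeric-prefix, else 0); the in-memory reference evaluator
reproduces this, including SQLite's cross-type ordering and numeric
affinity for text literals on numeric columns, so all three execution
routes (ARM SQL, Node+Path scan, brute force) are exactly interchangeable.
An archetype that is both standalone and embedded is queried in its
standalone table only; widening to all containing tables is a configuration
decision (`division_query_scope`) because the right scope depends on the
concept's semantics.

The Node+Path backend stores one row per populated leaf field — instance
key, repetition ordinal, full denormalized path text, typed-prefix
serialized value (`s:`/`i:`/`f:`) — one table per concept, only the
instance key indexed.  The path redundancy and the full scans it forces are
the phenomenon under comparison and are deliberately not optimized away.
Bookkeeping rows (`~key` registration, `~rep` empty-repetition markers,
`~parent` slot links) carry a `~` prefix so they never collide with leaf
paths.  Nested multiple-occurrence groups are not supported by this
backend's ordinal encoding (the suite has none; the ARM backend supports
them generally).

### Generalized/specialized translation

Each lab panel archetype maps onto the generalized name/value/unit
archetype through an EAV mapping file: per analyte, a name entry (display
name, language set) and field entries (magnitude/units → result/result
unit).  A specialized condition becomes a same-repetition pair (name
equality + translated comparison); distinct analytes bind distinct
repetitions of the same instance, so a multi-analyte search means "one test
instance satisfying all thresholds", and cross-archetype searches intersect
at subject level.  The reverse direction rewrites a generalized query into
one query per covering panel and unions the results.  Instance translation
turns each populated analyte into one repetition, rendering magnitudes as
canonical decimal text (the generalized result field is text); the
generalized archetype's own mandatory identification item must be supplied
by the caller since panels do not carry one.

## The synthetic workload

The generator emulates an integrated-viewer hospital workload: patients
with demographics and an assigned clinician; imaging requests each carrying
one exam (linked through the request→exam slot) with repeated images; lab
requests answered either by one of five concrete panels or by the
generalized archetype with repeated name/value/unit results.

Per-entity counts follow (minimum, mean, maximum) triples — patients per
clinician (1, 7, 50), imaging requests per patient (1, 3, 26), images per
exam (1, 363, 10 664), lab tests per patient (1, 23, 425), results per
generalized test (1, 168, 4 477) — drawn from a log-normal (σ = 1, mean as
stated), rounded and truncated; the heavy right tail matches the extreme
maxima.  The volume-heavy counts (images, lab tests, results) multiply by a
scale factor (default 0.05, the desk-scale setting: roughly 200 patients,
~3 000 instances, ~15 000 relational rows, seconds to load).  The scaled
mean of lab tests per patient is floored at six — one more than the number
of panels — and each patient's first tests cycle through the panels in a
random order before following the mix weights, so cross-panel patient
searches remain satisfiable at small scale; without the floor a 0.05 scale
leaves almost no patient with all five panels and the five-panel search
degenerates to the empty set.

Analyte values are normal around clinical reference midpoints, clipped to
plausible ranges, with spreads chosen so that every search threshold
(PaO₂ ≥ 129/229 mmHg, PaCO₂ ≥ 27 mmHg, pH ≥ 7.3, SaO₂ ≥ 99 %, CaO₂ ≥ 17 %,
red cells ≥ 2×10¹²/L, ALP ≥ 50 IU/L, TSH ≥ 0.3 µIU/mL, Na ≥ 140 mmol/L)
has probability mass on both sides — searches select nonempty,
non-universal patient sets.  The generalized tests draw from a separate
pool of analyte names so generalized data stays organic.  What the
generator does **not** emulate: clinical correlations between analytes,
longitudinal trajectories, missingness structure, real terminology
bindings, or full-scale volumes.  Passing tests therefore demonstrate
mapping/storage/query correctness and the direction of backend differences
on a workload-shaped dataset — not absolute performance on hospital data.

## Benchmark and measurement protocol

The seven tests (20 queries, ids 1.1–7.2) bind their minimum / average /
maximum variants to the entities at those extremes of the loaded dataset
(ties broken by smallest key).  Correctness gates performance: all queries
must produce identical result digests on both backends before any timing.

Timing uses fresh connections per query per repetition with the engine page
cache minimized (`PRAGMA cache_size = 16`), one untimed execution to absorb
connection/schema setup, and a timed block of n executions where n is
calibrated per backend and test group so every block lasts ~10 ms — equal
amplification within a group, so variant comparisons are fair.  Garbage
collection is disabled during timed blocks.  Reports carry the mean over
repetitions (the repetition protocol's statistic) and the minimum (the
noise-robust estimate of intrinsic cost), plus a per-query drift estimate —
the larger of the split-half difference of minima and the median-minus-min
spread.  Ordinal comparisons between scenario variants use the minimum and
treat differences below drift as statistical ties: a variant returning two
extra rows on a fixed-cost scan differs by microseconds, below timer drift
on any host, and reference measurements of this workload show exactly such
inversions between adjacent variants.  Absolute times are hardware-bound
and only reported, never asserted against anything external; the asserted
properties are ordinal — Node+Path at least as slow as ARM on every
patient-searching query, Node+Path footprint (file size after VACUUM)
larger than ARM's, and within-group times non-decreasing up to measured
drift.

## Numerical and degenerate-input choices

Floats round-trip exactly (IEEE-754 through SQLite REAL and through
`repr` in the typed-prefix encoding).  Empty repetition lists round-trip as
empty lists, not absent nodes; absent optional composites and all-None
leaves are dropped by normalization before structural comparison.
Duplicate identification values surface as unique-index violations on both
backends (the Node+Path backend enforces the constraint in code, since its
only index is the instance key).  Empty schemas emit empty DDL; migrations
over empty sources succeed trivially; a migration missing a mapping for a
NOT NULL target column aborts before copying, and a row-count mismatch
rolls back.

## Known limitations

The archetype dialect is a minimal structured-text capture of what the
mapping consumes (typed items, occurrences, slots, specialization lineage,
ontology texts) — not ADL: value-set constraints, terminology bindings and
annotations are out of scope, which also limits version classification to
structural compatibility.  SQLite has no clustered indexes; the model
preserves the clustered/non-clustered distinction and the emulation
(INTEGER PRIMARY KEY rowid order, or a UNIQUE index plus comment) is
recorded in the DDL.  The Node+Path backend's ordinal encoding supports one
level of repetition nesting.  Benchmark timings at desk scale resolve
order-of-magnitude differences (backend comparisons) reliably and
near-tied variant comparisons only up to measured drift.
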