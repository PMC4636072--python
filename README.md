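# armdb — archetype relational mapping for openEHR-style persistence

Two-level modelling separates a small, stable reference model from the
volatile clinical concepts expressed as **archetypes** (constraint models of
single concepts — a lab test, an imaging exam — built from typed data items,
collections and slots) and **templates** (local specializations of
archetypes).  The persistence layer is where this architecture usually
founders: the generic Node+Path store — an entity–attribute–value table of
`<node path, serialized value>` rows — is flexible but slow and bulky, while
a hand-designed relational database hard-wires the domain model it was meant
to escape.

`armdb` implements **archetype relational mapping (ARM)**: it *generates* a
relational schema from archetypes plus templates that carry two persistence
constraints — an **identification data item** (IDI, one per archetype,
occurrence 0..1 or 1..1, mapped to the unique clustered key) and **query
data items** (QDIs, mapped to non-clustered indexes).  The mapping rules
are, in brief:

1. each archetype maps to a table; compatible revisions share it;
2. a single-occurrence basic item becomes a column (its basic data type —
   `DvQuantity`, `DvCodedText`, … — expands to typed fields, e.g.
   `magnitude FLOAT, units NVARCHAR`); a multiple-occurrence item becomes a
   standalone table with a foreign key;
3. the IDI becomes the unique clustered key, or an invisible generated `id`
   stands in;
4. QDIs get non-clustered indexes;
5. a slot with upper bound `*` becomes a foreign key in the target
   archetype's table; with upper bound `1` the target's items are embedded
   inline;
6. single-occurrence collections flatten; multiple-occurrence collections
   become child tables;
7. QDIs propagate (like the IDI, as the foreign key) into the child tables
   of multiple-occurrence slots/collections, indexed, unless suppressed in
   the template;
8. names derive from archetype and item names, version-stripped for shared
   tables, deterministically shortened when over the identifier limit.

The package also provides: instance persistence and retrieval through the
generated schema; a backend-neutral query layer (stepwise simple statements,
key-set intersection, subject-level grouping); query and instance
translation between specialized archetypes (concrete lab panels) and a
generalized name/value/unit archetype via EAV mapping files; a **Node+Path
baseline backend** with identical contracts; a seeded synthetic-data
generator shaped like an integrated-viewer hospital workload; and a
correctness-gated benchmark of seven clinical tests (20 queries).

## Worked example

```python
import sqlite3
from armdb import (ArmStore, build_fixture_suite, map_schema,
                   load_instances, query, Condition)
from armdb.query import SUBJECT
from armdb.synth import DatasetParams, generate_dataset

suite = build_fixture_suite()          # 17 archetypes, 5 templates, 5 EAV maps
schema = map_schema(suite.archetypes, suite.templates, suite.eav_mappings)
print(f"{len(suite.archetypes)} archetypes -> {len(schema.tables)} tables")

instances = list(generate_dataset(DatasetParams(seed=1, n_patients=200, scale=0.05)))
arm = ArmStore.deploy(schema, suite.by_id, sqlite3.connect(":memory:"))
load_instances(arm, instances)

blood_gases = "openEHR-EHR-OBSERVATION.lab_test-blood_gases.v1"
spec = query(blood_gases, [Condition("paO2", "magnitude", ">=", 129)],
             group_unit=SUBJECT)
hits = arm.run_query(spec)
print(f"patients with PaO2 >= 129 mmHg: {len(hits)} of 200")
print("first five:", hits.rows[:5])
```

prints

```
17 archetypes -> 12 tables
patients with PaO2 >= 129 mmHg: 103 of 200
first five: ['P00001', 'P00006', 'P00010', 'P00011', 'P00016']
```

The 12 tables include `DPersonPatient` (clustered unique key
`patientIdentifier_identifier_id`, assembled by embedding the patient's
identifier/name/details cluster archetypes through single-occurrence slots)
and `OLabTestGeneralStructureResult`, the child table of the generalized
lab archetype's repeating result group, which carries the propagated,
non-clustered-indexed `OLabTestGeneral_patient_value` column that makes
patient-centred result retrieval a single-table query.  The patient search
above runs against the blood-gas panel's own standalone table; on the
Node+Path backend the same query must scan the concept's path/value rows,
which is the performance and storage gap the benchmark quantifies.

## Command line

```sh
armdb schema --dialect sqlite --out schema.sql     # emit the generated DDL
armdb synth --seed 1 --patients 200 --scale 0.05 --out data.jsonl
armdb load data.jsonl --backend arm --db arm.sqlite
armdb query spec.json --backend nodepath --db np.sqlite --group-by subject
armdb bench --seed 1 --patients 200 --scale 0.05 --reps 10 --out report.json
armdb bench-csv report.json report.csv
```

`armdb bench` loads both backends with the identical dataset, refuses to
time anything unless every query's result digest agrees across backends,
and reports per-query mean/minimum times and on-disk footprints.

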