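"""The worked 17-archetype clinical-viewer suite.

The suite reconstructs an integrated-viewer (IV) workload: patient
demographics (a person archetype composing identifier, name and details
clusters), imaging exam requests with their exams and images, lab test
requests, the generalized name/value/unit lab result archetype, and five
specialized lab panels (blood gases, full blood count, liver function,
thyroid, urea & electrolytes) mapped onto the generalized form by EAV
mapping files.  Five templates carry the ARM identification/query-item
constraints.

Archetype internals are reconstructed minimally: only the items the
workload's queries and schema reference, plus structural plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .archetype import Archetype, parse_archetype
from .template import (
    EavMapping,
    Template,
    parse_eav_mapping,
    parse_template,
)

GENERALIZED_LAB = "openEHR-EHR-OBSERVATION.lab_test-general.v1"

PANEL_ARCHETYPES = {
    "blood_gases": "openEHR-EHR-OBSERVATION.lab_test-blood_gases.v1",
    "full_blood_count": "openEHR-EHR-OBSERVATION.lab_test-full_blood_count.v1",
    "liver_function": "openEHR-EHR-OBSERVATION.lab_test-liver_function.v1",
    "thyroid": "openEHR-EHR-OBSERVATION.lab_test-thyroid.v1",
    "urea_and_electrolytes": "openEHR-EHR-OBSERVATION.lab_test-urea_and_electrolytes.v1",
}

PERSON_PATIENT = "openEHR-DEMOGRAPHIC-PERSON.person-patient.v1"
REQUEST_IMAGING = "openEHR-EHR-INSTRUCTION.request-imaging_exam.v1"
IMAGING_EXAM = "openEHR-EHR-OBSERVATION.imaging_exam.v1"
REQUEST_LAB = "openEHR-EHR-INSTRUCTION.request-lab_test.v1"
LAB_TEST = "openEHR-EHR-OBSERVATION.lab_test.v1"


@dataclass
class FixtureSuite:
    archetypes: list
    templates: list
    eav_mappings: list

    @property
    def by_id(self) -> dict:
        return {a.id_text: a for a in self.archetypes}

    def archetype(self, archetype_id: str) -> Archetype:
        return self.by_id[archetype_id]

    def template_for(self, archetype_id: str) -> Template:
        for t in self.templates:
            if t.archetype_id == archetype_id:
                return t
        raise KeyError(f"no template for {archetype_id}")

    def mapping_for(self, specialized_id: str) -> EavMapping:
        for m in self.eav_mappings:
            if m.specialized_archetype_id == specialized_id:
                return m
        raise KeyError(f"no EAV mapping for {specialized_id}")


def _data_dir():
    return resources.files("armdb.data")


def build_fixture_suite() -> FixtureSuite:
    """Load the shipped archetype, template and EAV mapping fixtures."""
    root = _data_dir()
    archetypes = []
    for entry in sorted(root.joinpath("archetypes").iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            archetypes.append(parse_archetype(entry.read_text(encoding="utf-8")))
    templates = []
    for entry in sorted(root.joinpath("templates").iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            templates.append(parse_template(entry.read_text(encoding="utf-8")))
    eav_mappings = []
    for entry in sorted(root.joinpath("eav").iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".xml"):
            specialized_id = entry.name[: -len(".xml")]
            eav_mappings.append(
                parse_eav_mapping(entry.read_text(encoding="utf-8"), specialized_id)
            )
    # deterministic ordering: demographics, then workflow order, then panels
    order = [
        PERSON_PATIENT,
        "openEHR-DEMOGRAPHIC-CLUSTER.person_identifier.v1",
        "openEHR-DEMOGRAPHIC-PARTY_IDENTITY.person_name.v1",
        "openEHR-DEMOGRAPHIC-ITEM_TREE.person details.v1",
        REQUEST_IMAGING,
        IMAGING_EXAM,
        REQUEST_LAB,
        LAB_TEST,
        GENERALIZED_LAB,
        *PANEL_ARCHETYPES.values(),
        "openEHR-EHR-CLUSTER.lab_result_annotation.v1",
        "openEHR-EHR-CLUSTER.organisation.v1",
        "openEHR-EHR-CLUSTER.person_name.v1",
    ]
    rank = {aid: i for i, aid in enumerate(order)}
    archetypes.sort(key=lambda a: rank.get(a.id_text, len(order)))
    return FixtureSuite(archetypes, templates, eav_mappings)
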