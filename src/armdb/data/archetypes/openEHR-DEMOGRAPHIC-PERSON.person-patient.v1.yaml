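archetype_id: openEHR-DEMOGRAPHIC-PERSON.person-patient.v1
nodes:
- name: patientIdentifier
  kind: slot
  target: openEHR-DEMOGRAPHIC-CLUSTER.person_identifier.v1
  occurrence: 1..1
  text:
    en: Patient identifier
- name: personName
  kind: slot
  target: openEHR-DEMOGRAPHIC-PARTY_IDENTITY.person_name.v1
  occurrence: 0..1
  text:
    en: Person name
- name: personDetails
  kind: slot
  target: openEHR-DEMOGRAPHIC-ITEM_TREE.person details.v1
  occurrence: 0..1
  text:
    en: Person details
- name: assignedClinician
  kind: basic
  type: DvIdentifier
  occurrence: 0..1
  text:
    en: Assigned clinician
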