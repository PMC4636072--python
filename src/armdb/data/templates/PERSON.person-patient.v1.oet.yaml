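template_id: PERSON.person-patient.v1.oet
archetype_id: openEHR-DEMOGRAPHIC-PERSON.person-patient.v1
arm:
  identification_item: patientIdentifier/identifier
  query_items: []
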