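template_id: OBSERVATION.lab_test-general.v1.oet
archetype_id: openEHR-EHR-OBSERVATION.lab_test-general.v1
arm:
  identification_item: id
  query_items:
  - receiverOrderIdentifier
  - patient
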