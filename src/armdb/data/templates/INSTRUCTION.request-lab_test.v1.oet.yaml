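template_id: INSTRUCTION.request-lab_test.v1.oet
archetype_id: openEHR-EHR-INSTRUCTION.request-lab_test.v1
arm:
  identification_item: receiverIdentifier
  query_items:
  - requestorIdentifier
  - patient
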