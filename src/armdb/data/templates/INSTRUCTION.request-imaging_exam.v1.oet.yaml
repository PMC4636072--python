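template_id: INSTRUCTION.request-imaging_exam.v1.oet
archetype_id: openEHR-EHR-INSTRUCTION.request-imaging_exam.v1
arm:
  identification_item: id
  query_items:
  - requestorIdentifier
  - patient
  - receiverIdentifier
  suppressed_propagations:
  - - examItems
    - requestorIdentifier
  - - examItems
    - receiverIdentifier
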