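archetype_id: openEHR-EHR-INSTRUCTION.request-lab_test.v1
nodes:
- name: receiverIdentifier
  kind: basic
  type: DvText
  occurrence: 1..1
  text:
    en: Receiver identifier
- name: requestorIdentifier
  kind: basic
  type: DvText
  occurrence: 0..1
  text:
    en: Requestor identifier
- name: patient
  kind: basic
  type: DvText
  occurrence: 1..1
  text:
    en: Patient
- name: requestDateTime
  kind: basic
  type: DvDateTime
  occurrence: 0..1
  text:
    en: Request date time
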