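archetype_id: openEHR-EHR-OBSERVATION.lab_test-urea_and_electrolytes.v1
parent_id: openEHR-EHR-OBSERVATION.lab_test.v1
nodes:
- name: receiverOrderIdentifier
  kind: basic
  type: DvText
  occurrence: 0..1
  text:
    en: Receiver order identifier
- name: patient
  kind: basic
  type: DvText
  occurrence: 1..1
  text:
    en: Patient
- name: testDateTime
  kind: basic
  type: DvDateTime
  occurrence: 0..1
  text:
    en: Test date time
- name: annotation
  kind: slot
  target: openEHR-EHR-CLUSTER.lab_result_annotation.v1
  occurrence: 0..1
  text:
    en: Annotation
- name: sodium
  kind: basic
  type: DvQuantity
  occurrence: 0..1
  text:
    en: Sodium
- name: potassium
  kind: basic
  type: DvQuantity
  occurrence: 0..1
  text:
    en: Potassium
- name: urea
  kind: basic
  type: DvQuantity
  occurrence: 0..1
  text:
    en: Urea
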