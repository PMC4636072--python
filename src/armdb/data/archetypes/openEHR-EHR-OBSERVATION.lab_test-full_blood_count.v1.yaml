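archetype_id: openEHR-EHR-OBSERVATION.lab_test-full_blood_count.v1
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
- name: redCellCount
  kind: basic
  type: DvQuantity
  occurrence: 0..1
  text:
    en: Red cell count
- name: whiteCellCount
  kind: basic
  type: DvQuantity
  occurrence: 0..1
  text:
    en: White cell count
- name: haemoglobin
  kind: basic
  type: DvQuantity
  occurrence: 0..1
  text:
    en: Haemoglobin
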