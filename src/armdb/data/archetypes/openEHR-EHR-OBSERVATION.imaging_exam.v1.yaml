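archetype_id: openEHR-EHR-OBSERVATION.imaging_exam.v1
nodes:
- name: id
  kind: basic
  type: DvIdentifier
  occurrence: 1..1
  text:
    en: Id
- name: receiverOrderIdentifier
  kind: basic
  type: DvIdentifier
  occurrence: 0..1
  text:
    en: Receiver order identifier
- name: patient
  kind: basic
  type: DvText
  occurrence: 1..1
  text:
    en: Patient
- name: examDateTime
  kind: basic
  type: DvDateTime
  occurrence: 0..1
  text:
    en: Exam date time
- name: reportText
  kind: basic
  type: DvText
  occurrence: 0..1
  text:
    en: Report text
- name: imageDetails
  kind: cluster
  occurrence: 0..*
  text:
    en: Image details
  children:
  - name: image
    kind: basic
    type: DvMultimedia
    occurrence: 0..1
    text:
      en: Image
  - name: imageNumber
    kind: basic
    type: DvCount
    occurrence: 0..1
    text:
      en: Image number
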