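archetype_id: openEHR-EHR-INSTRUCTION.request-imaging_exam.v1
nodes:
- name: id
  kind: basic
  type: DvIdentifier
  occurrence: 1..1
  text:
    en: Id
- name: requestorIdentifier
  kind: basic
  type: DvText
  occurrence: 0..1
  text:
    en: Requestor identifier
- name: receiverIdentifier
  kind: basic
  type: DvText
  occurrence: 0..1
  text:
    en: Receiver identifier
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
- name: examName
  kind: basic
  type: DvText
  occurrence: 0..1
  text:
    en: Exam name
- name: requesterOrganisation
  kind: slot
  target: openEHR-EHR-CLUSTER.organisation.v1
  occurrence: 0..1
  text:
    en: Requester organisation
- name: requestorName
  kind: slot
  target: openEHR-EHR-CLUSTER.person_name.v1
  occurrence: 0..1
  text:
    en: Requestor name
- name: examItems
  kind: slot
  target: openEHR-EHR-OBSERVATION.imaging_exam.v1
  occurrence: 0..*
  text:
    en: Exam items
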