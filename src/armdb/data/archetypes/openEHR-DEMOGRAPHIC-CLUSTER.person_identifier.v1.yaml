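archetype_id: openEHR-DEMOGRAPHIC-CLUSTER.person_identifier.v1
nodes:
- name: identifier
  kind: basic
  type: DvIdentifier
  occurrence: 1..1
  text:
    en: Identifier
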