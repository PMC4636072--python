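archetype_id: openEHR-EHR-CLUSTER.organisation.v1
nodes:
- name: name
  kind: basic
  type: DvText
  occurrence: 0..1
  text:
    en: Name
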