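archetype_id: openEHR-DEMOGRAPHIC-ITEM_TREE.person details.v1
nodes:
- name: sex
  kind: basic
  type: DvCodedText
  occurrence: 0..1
  text:
    en: Sex
- name: birthDate
  kind: basic
  type: DvDateTime
  occurrence: 0..1
  text:
    en: Birth date
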