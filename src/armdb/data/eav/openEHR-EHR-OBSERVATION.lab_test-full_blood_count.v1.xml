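<eav name="openEHR-EHR-OBSERVATION.lab_test-general.v1"></eav>
<eavAttributeName name="[Red cell count]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[Red cell count]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[Red cell count]/value/units">[Result unit]/value/value</eavAttributeField>
<eavAttributeName name="[White cell count]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[White cell count]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[White cell count]/value/units">[Result unit]/value/value</eavAttributeField>
<eavAttributeName name="[Haemoglobin]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[Haemoglobin]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[Haemoglobin]/value/units">[Result unit]/value/value</eavAttributeField>
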