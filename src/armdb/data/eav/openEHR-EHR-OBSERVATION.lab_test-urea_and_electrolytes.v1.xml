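<eav name="openEHR-EHR-OBSERVATION.lab_test-general.v1"></eav>
<eavAttributeName name="[Sodium]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[Sodium]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[Sodium]/value/units">[Result unit]/value/value</eavAttributeField>
<eavAttributeName name="[Potassium]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[Potassium]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[Potassium]/value/units">[Result unit]/value/value</eavAttributeField>
<eavAttributeName name="[Urea]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[Urea]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[Urea]/value/units">[Result unit]/value/value</eavAttributeField>
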