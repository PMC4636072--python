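<eav name="openEHR-EHR-OBSERVATION.lab_test-general.v1"></eav>
<eavAttributeName name="[PaO2]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[PaO2]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[PaO2]/value/units">[Result unit]/value/value</eavAttributeField>
<eavAttributeName name="[PaCO2]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[PaCO2]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[PaCO2]/value/units">[Result unit]/value/value</eavAttributeField>
<eavAttributeName name="[Arterial pH]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[Arterial pH]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[Arterial pH]/value/units">[Result unit]/value/value</eavAttributeField>
<eavAttributeName name="[SaO2]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[SaO2]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[SaO2]/value/units">[Result unit]/value/value</eavAttributeField>
<eavAttributeName name="[CaO2]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[CaO2]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[CaO2]/value/units">[Result unit]/value/value</eavAttributeField>
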