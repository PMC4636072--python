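<eav name="openEHR-EHR-OBSERVATION.lab_test-general.v1"></eav>
<eavAttributeName name="[Alkaline phosphatase]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[Alkaline phosphatase]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[Alkaline phosphatase]/value/units">[Result unit]/value/value</eavAttributeField>
<eavAttributeName name="[Alanine aminotransferase]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[Alanine aminotransferase]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[Alanine aminotransferase]/value/units">[Result unit]/value/value</eavAttributeField>
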