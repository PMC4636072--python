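<eav name="openEHR-EHR-OBSERVATION.lab_test-general.v1"></eav>
<eavAttributeName name="[Thyroid stimulating hormone]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[Thyroid stimulating hormone]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[Thyroid stimulating hormone]/value/units">[Result unit]/value/value</eavAttributeField>
<eavAttributeName name="[Free thyroxine]" set="en">[Test item]/value/value</eavAttributeName>
<eavAttributeField name="[Free thyroxine]/value/magnitude">[Result]/value/value</eavAttributeField>
<eavAttributeField name="[Free thyroxine]/value/units">[Result unit]/value/value</eavAttributeField>
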