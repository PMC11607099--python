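<?xml version="1.0" encoding="UTF-8"?>
<!-- Traumatic brain injury severity bands over the total Glasgow Coma
     Scale: 3-8 severe, 9-12 moderate, 13-15 mild. -->
<definitions xmlns="https://www.omg.org/spec/DMN/20191111/MODEL/"
             id="gcs_severity_def" name="TBI severity banding">
  <decision id="gcs_severity" name="TBI severity banding">
    <decisionTable hitPolicy="UNIQUE">
      <input label="gcs">
        <inputExpression typeRef="number"><text>gcs</text></inputExpression>
        <inputValues><text>3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15</text></inputValues>
      </input>
      <output name="tbi_severity" typeRef="string"/>
      <rule>
        <inputEntry><text>[3..8]</text></inputEntry>
        <outputEntry><text>"severe"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>[9..12]</text></inputEntry>
        <outputEntry><text>"moderate"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>[13..15]</text></inputEntry>
        <outputEntry><text>"mild"</text></outputEntry>
      </rule>
    </decisionTable>
  </decision>
</definitions>
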