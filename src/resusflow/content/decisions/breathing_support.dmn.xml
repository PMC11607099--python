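<?xml version="1.0" encoding="UTF-8"?>
<!-- Absent unilateral breath sounds in a trauma patient are treated as
     tension physiology until proven otherwise: immediate decompression.
     FIRST hit policy: rows are ordered by escalation. -->
<definitions xmlns="https://www.omg.org/spec/DMN/20191111/MODEL/"
             id="breathing_support_def" name="Breathing support">
  <decision id="breathing_support" name="Breathing support">
    <decisionTable hitPolicy="FIRST">
      <input label="spo2">
        <inputExpression typeRef="number"><text>spo2</text></inputExpression>
      </input>
      <input label="breath_sounds">
        <inputExpression typeRef="string"><text>breath_sounds</text></inputExpression>
        <inputValues><text>"normal", "diminished", "absent_left", "absent_right"</text></inputValues>
      </input>
      <output name="breathing_action" typeRef="string"/>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>"absent_left", "absent_right"</text></inputEntry>
        <outputEntry><text>"chest_decompression"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>"diminished"</text></inputEntry>
        <outputEntry><text>"oxygen"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>&lt; 92</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"oxygen"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"none"</text></outputEntry>
      </rule>
    </decisionTable>
  </decision>
</definitions>
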