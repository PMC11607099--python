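<?xml version="1.0" encoding="UTF-8"?>
<definitions xmlns="https://www.omg.org/spec/DMN/20191111/MODEL/"
             id="airway_management_def" name="Airway management">
  <decision id="airway_management" name="Airway management">
    <decisionTable hitPolicy="UNIQUE">
      <input label="airway_patent">
        <inputExpression typeRef="boolean"><text>airway_patent</text></inputExpression>
      </input>
      <output name="airway_action" typeRef="string"/>
      <rule>
        <inputEntry><text>false</text></inputEntry>
        <outputEntry><text>"secure_airway"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>true</text></inputEntry>
        <outputEntry><text>"none"</text></outputEntry>
      </rule>
    </decisionTable>
  </decision>
</definitions>
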