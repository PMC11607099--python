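<?xml version="1.0" encoding="UTF-8"?>
<!-- Tranexamic acid: 1000 mg loading dose for actively bleeding patients or
     shock class II or worse, only within 3 h of injury.  FIRST policy: the
     window exclusion row precedes the indication rows. -->
<definitions xmlns="https://www.omg.org/spec/DMN/20191111/MODEL/"
             id="txa_indication_def" name="Tranexamic acid indication">
  <decision id="txa_indication" name="Tranexamic acid indication">
    <decisionTable hitPolicy="FIRST">
      <input label="shock_class">
        <inputExpression typeRef="string"><text>shock_class</text></inputExpression>
        <inputValues><text>"I", "II", "III", "IV"</text></inputValues>
      </input>
      <input label="actively_bleeding">
        <inputExpression typeRef="boolean"><text>actively_bleeding</text></inputExpression>
      </input>
      <input label="minutes_since_injury">
        <inputExpression typeRef="number"><text>minutes_since_injury</text></inputExpression>
      </input>
      <output name="txa_indicated" typeRef="boolean"/>
      <output name="txa_dose_mg" typeRef="number"/>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>&gt;= 180</text></inputEntry>
        <outputEntry><text>false</text></outputEntry>
        <outputEntry><text>0</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>true</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>true</text></outputEntry>
        <outputEntry><text>1000</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>"II", "III", "IV"</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>true</text></outputEntry>
        <outputEntry><text>1000</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>false</text></outputEntry>
        <outputEntry><text>0</text></outputEntry>
      </rule>
    </decisionTable>
  </decision>
</definitions>
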