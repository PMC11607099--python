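<?xml version="1.0" encoding="UTF-8"?>
<!-- ATLS-style hemorrhagic shock staging as a FIRST-policy table: rows for
     class IV come first, then III, then II, with a wildcard row yielding I.
     Each row tests a single input band, so the table computes the worst
     (maximum) class over all inputs; band boundaries belong to the higher
     class.  Mirrors resusflow.decisions.shock_class, which the tests use as
     an independent cross-check. -->
<definitions xmlns="https://www.omg.org/spec/DMN/20191111/MODEL/"
             id="shock_classification_def" name="Hemorrhagic shock classification">
  <decision id="shock_classification" name="Hemorrhagic shock classification">
    <decisionTable hitPolicy="FIRST">
      <input label="heart_rate">
        <inputExpression typeRef="number"><text>heart_rate</text></inputExpression>
      </input>
      <input label="systolic_bp">
        <inputExpression typeRef="number"><text>systolic_bp</text></inputExpression>
      </input>
      <input label="resp_rate">
        <inputExpression typeRef="number"><text>resp_rate</text></inputExpression>
      </input>
      <input label="mental_status">
        <inputExpression typeRef="string"><text>mental_status</text></inputExpression>
        <inputValues><text>"alert", "anxious", "confused", "lethargic", "unresponsive"</text></inputValues>
      </input>
      <input label="est_blood_loss_fraction">
        <inputExpression typeRef="number"><text>est_blood_loss_fraction</text></inputExpression>
      </input>
      <output name="shock_class" typeRef="string"/>
      <rule>
        <inputEntry><text>&gt;= 140</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"IV"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>&lt; 70</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"IV"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>&gt;= 35</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"IV"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>"unresponsive"</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"IV"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>&gt;= 0.4</text></inputEntry>
        <outputEntry><text>"IV"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>&gt;= 120</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"III"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>&lt;= 90</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"III"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>&gt;= 30</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"III"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>"confused", "lethargic"</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"III"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>&gt;= 0.3</text></inputEntry>
        <outputEntry><text>"III"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>&gt;= 100</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"II"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>&lt;= 100</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"II"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>&gt;= 20</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"II"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>"anxious"</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"II"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>&gt;= 0.15</text></inputEntry>
        <outputEntry><text>"II"</text></outputEntry>
      </rule>
      <rule>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <inputEntry><text>-</text></inputEntry>
        <outputEntry><text>"I"</text></outputEntry>
      </rule>
    </decisionTable>
  </decision>
</definitions>
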