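<?xml version="1.0" encoding="UTF-8"?>
<!--
  Resuscitation subprocess: CPR loop until return of spontaneous circulation
  (ROSC).  Starting it also starts the dedicated resuscitation timer of the
  root instance.  Declares rosc as an output variable.
-->
<definitions xmlns="http://www.omg.org/spec/BPMN/20100524/MODEL"
             xmlns:rf="https://resusflow.dev/schema/bpmn-ext"
             targetNamespace="https://resusflow.dev/schema/bpmn-ext">
  <process id="resuscitation" name="Resuscitation (CPR)" rf:timerName="resuscitation">
    <extensionElements>
      <rf:outputVariable name="rosc"/>
    </extensionElements>
    <startEvent id="r_start"/>
    <userTask id="r_cpr" name="Start chest compressions / ventilation (30:2)" rf:priority="critical">
      <extensionElements>
        <rf:formField name="performed" type="boolean" required="true"/>
      </extensionElements>
    </userTask>
    <userTask id="r_rhythm" name="Rhythm check, defibrillate if shockable" rf:priority="critical">
      <extensionElements>
        <rf:formField name="shockable" type="boolean" required="true"/>
      </extensionElements>
    </userTask>
    <userTask id="r_rosc" name="Return of spontaneous circulation?" rf:priority="critical">
      <extensionElements>
        <rf:formField name="rosc" type="boolean" required="true"/>
      </extensionElements>
    </userTask>
    <exclusiveGateway id="r_x" default="fr_loop"/>
    <endEvent id="r_end"/>
    <sequenceFlow id="fr1" sourceRef="r_start" targetRef="r_cpr"/>
    <sequenceFlow id="fr2" sourceRef="r_cpr" targetRef="r_rhythm"/>
    <sequenceFlow id="fr3" sourceRef="r_rhythm" targetRef="r_rosc"/>
    <sequenceFlow id="fr4" sourceRef="r_rosc" targetRef="r_x"/>
    <sequenceFlow id="fr_rosc" sourceRef="r_x" targetRef="r_end">
      <conditionExpression>rosc == true</conditionExpression>
    </sequenceFlow>
    <sequenceFlow id="fr_loop" sourceRef="r_x" targetRef="r_cpr"/>
  </process>
</definitions>
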