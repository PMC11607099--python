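<?xml version="1.0" encoding="UTF-8"?>
<!--
  Circulatory shock subprocess: vascular access, volume/blood-product
  resuscitation and labs.  Started from the C stage of the main model (or at
  any time as a non-interrupting parallel subprocess).  Declares
  transfusion_started as an output variable merged back into the caller.
-->
<definitions xmlns="http://www.omg.org/spec/BPMN/20100524/MODEL"
             xmlns:rf="https://resusflow.dev/schema/bpmn-ext"
             targetNamespace="https://resusflow.dev/schema/bpmn-ext">
  <process id="circulatory_shock" name="Circulatory shock management">
    <extensionElements>
      <rf:outputVariable name="transfusion_started"/>
    </extensionElements>
    <startEvent id="cs_start"/>
    <userTask id="cs_access" name="Establish two large-bore IV lines" rf:priority="critical">
      <extensionElements>
        <rf:formField name="performed" type="boolean" required="true"/>
      </extensionElements>
    </userTask>
    <userTask id="cs_volume" name="Start warmed volume and blood products" rf:priority="critical"
              rf:intervention="transfusion" rf:interventionCondition="transfusion_started == true">
      <extensionElements>
        <rf:formField name="transfusion_started" type="boolean" required="true"/>
      </extensionElements>
    </userTask>
    <userTask id="cs_labs" name="Draw labs, blood gas and crossmatch">
      <extensionElements>
        <rf:formField name="performed" type="boolean" required="true"/>
      </extensionElements>
    </userTask>
    <endEvent id="cs_end"/>
    <sequenceFlow id="fcs1" sourceRef="cs_start" targetRef="cs_access"/>
    <sequenceFlow id="fcs2" sourceRef="cs_access" targetRef="cs_volume"/>
    <sequenceFlow id="fcs3" sourceRef="cs_volume" targetRef="cs_labs"/>
    <sequenceFlow id="fcs4" sourceRef="cs_labs" targetRef="cs_end"/>
  </process>
</definitions>
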