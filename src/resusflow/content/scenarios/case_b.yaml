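# Training case B: fall from a 6 m scaffold with severe traumatic brain
# injury (intracranial hemorrhage), an unstable pelvic injury, free fluid in
# the abdomen, and class-III hemorrhagic shock.
#
# SYNTHETIC FIXTURE PARAMETERS: numeric vitals, bleed rates and maps are
# this package's stand-ins (see case_a.yaml); constrained by the case
# definition only (class-III shock; severe TBI means GCS <= 8).
scenario_id: B
synthetic: true
description: >
  Man fell from a 6 m scaffold: severe traumatic brain injury with
  intracranial hemorrhage, unstable pelvic injury, free abdominal fluid,
  class-III hemorrhagic shock.
injury_time_offset_min: 40
initial:
  heart_rate: 116
  systolic_bp: 96
  spo2: 91
  resp_rate: 30
  gcs: 6
  blood_volume_fraction: 0.68
  airway_patent: false
  tension_physiology: false
region_ais:
  head_neck: 5
  abdomen: 3
  extremities_pelvis: 4
  external: 1
thoracic_injury: null
neuro_injury:
  intracranial_hemorrhage: true
  initial_gcs: 6
pelvis_unstable: true
free_abdominal_fluid: true
bleeds:
  - source: pelvis
    rate_per_min: 0.006
    controllable_by: [surgery_transfer]
    attenuators: {pelvic_binder: 0.25}
  - source: abdomen
    rate_per_min: 0.006
    controllable_by: [surgery_transfer]
applicable_interventions:
  [pelvic_binder, airway_secured, oxygen, txa, transfusion, surgery_transfer]
dynamics:
  hr_map: [[0.50, 160], [0.55, 145], [0.65, 125], [0.70, 110], [0.85, 95], [1.0, 75]]
  sbp_map: [[0.50, 40], [0.55, 70], [0.65, 90], [0.70, 100], [0.85, 110], [1.0, 120]]
  rr_map: [[0.50, 40], [0.65, 32], [0.85, 18], [1.0, 14]]
  txa_bleed_factor: 0.7
  txa_window_min: 180
  pelvic_binder_factor: 0.25
  transfusion_rate_per_min: 0.002
  spo2_decline_per_s: 0.05
  spo2_recovery_per_s: 0.1
  spo2_floor: 60
  spo2_ceiling: 97
  gcs_decline_sbp_threshold: 70
  gcs_decline_per_30s: 1
  death_sbp: 40
  death_volume_fraction: 0.5
perfect_run:
  - task: handover
    values: {gender: male, accident_type: fall, minutes_since_injury: 40}
  - task: c_assess
    values: {critical_bleeding: false, bleeding_source: none}
  - task: c_reeval
    values: {repeat_stage: none}
  - task: a_assess
    values: {airway_patent: "$truth"}
  - task: a_secure
    values: {performed: true}
  - task: a_reeval
    values: {repeat_stage: none}
  - task: b_assess
    values: {resp_rate: "$truth", spo2: "$truth", breath_sounds: "$truth"}
  - task: b_oxygen
    values: {performed: true}
  - task: b_reeval
    values: {repeat_stage: none}
  - task: circ_assess
    values:
      heart_rate: "$truth"
      systolic_bp: "$truth"
      resp_rate: "$truth"
      est_blood_loss_fraction: "$truth"
      mental_status: "$truth"
      actively_bleeding: "$truth"
  - task: txa_task
    values: {performed: true}
  - task: cs_access
    values: {performed: true}
  - task: cs_volume
    values: {transfusion_started: true}
  - task: cs_labs
    values: {performed: true}
  - task: circ_reeval
    values: {repeat_stage: none}
  - task: d_assess
    values: {gcs_eye: "$truth", gcs_verbal: "$truth", gcs_motor: "$truth"}
  - task: head_ct
    values: {performed: true}
  - task: d_reeval
    values: {repeat_stage: none}
  - task: e_exam
    values: {pelvis_unstable: "$truth", free_abdominal_fluid: "$truth", hypothermia_protection: true}
  - task: e_binder
    values: {performed: true}
  - task: e_abdomen
    values: {performed: true}
  - task: e_reeval
    values: {repeat_stage: none}
  - task: transfer_decision
    values: {transfer_to: OR}
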