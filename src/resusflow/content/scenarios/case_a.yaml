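# Training case A: blunt assault with a (tension) pneumothorax, a relevant
# bleeding scalp wound, and a splenic injury producing class-III hemorrhagic
# shock.
#
# SYNTHETIC FIXTURE PARAMETERS: the numeric vitals, bleed rates and
# piecewise-linear volume-to-vitals maps below are this package's own
# stand-ins, constrained only by the case definition (initial state must
# classify as shock class III; untreated death within 10-20 simulated
# minutes).  They are not measurements.
scenario_id: A
synthetic: true
description: >
  Male victim of a violent crime injured with a blunt weapon: pneumothorax,
  relevant bleeding scalp wound, splenic injury, class-III hemorrhagic shock.
injury_time_offset_min: 45
initial:
  heart_rate: 125
  systolic_bp: 90
  spo2: 88
  resp_rate: 32
  gcs: 14
  blood_volume_fraction: 0.65
  airway_patent: true
  tension_physiology: true
region_ais:
  head_neck: 1
  chest: 4
  abdomen: 4
  external: 2
thoracic_injury:
  tension_pneumothorax: true
  side: left
neuro_injury: null
pelvis_unstable: false
free_abdominal_fluid: true
bleeds:
  - source: scalp
    rate_per_min: 0.004
    controllable_by: [pressure_dressing, surgery_transfer]
  - source: spleen
    rate_per_min: 0.008
    controllable_by: [surgery_transfer]
applicable_interventions:
  [pressure_dressing, chest_decompression, chest_tube, airway_secured,
   oxygen, txa, transfusion, surgery_transfer]
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
    values: {gender: male, accident_type: blunt, minutes_since_injury: 45}
  - task: c_assess
    values: {critical_bleeding: true, bleeding_source: scalp}
  - task: c_control
    values: {performed: true}
  - task: c_reeval
    values: {repeat_stage: none}
  - task: a_assess
    values: {airway_patent: "$truth"}
  - task: a_reeval
    values: {repeat_stage: none}
  - task: b_assess
    values: {resp_rate: "$truth", spo2: "$truth", breath_sounds: "$truth"}
  - task: b_decompress
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
  - task: d_reeval
    values: {repeat_stage: none}
  - task: e_exam
    values: {pelvis_unstable: "$truth", free_abdominal_fluid: "$truth", hypothermia_protection: true}
  - task: e_abdomen
    values: {performed: true}
  - task: e_reeval
    values: {repeat_stage: none}
  - task: transfer_decision
    values: {transfer_to: OR}
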