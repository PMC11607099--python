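# Essential-treatment-step rubric: one point per item, 12 per scenario
# (9 generic + 3 scenario-specific).  Predicates are declarative patterns
# over a session record's audit events and applied interventions:
#
#   events:             all listed {kind, node[, payload]} events must occur
#   events_any:         at least one listed event must occur
#   interventions:      all listed {kind[, target]} interventions must occur
#   interventions_any:  at least one listed intervention must occur
#   ordered_tasks:      completions of the listed tasks must exist in
#                       non-decreasing time order (greedy subsequence match)
#   max_minutes_since_injury: latest allowed injury-to-intervention time
items:
  - item_id: cabcde_order
    description: Primary survey performed in cABCDE order
    scope: generic
    predicate:
      ordered_tasks: [c_assess, a_assess, b_assess, circ_assess, d_assess, e_exam]
  - item_id: handover_captured
    description: Handover information captured on arrival
    scope: generic
    predicate:
      events:
        - {kind: task_completed, node: handover}
  - item_id: airway_assessed
    description: Airway patency assessed
    scope: generic
    predicate:
      events:
        - {kind: task_completed, node: a_assess}
  - item_id: breathing_assessed
    description: Breathing assessed (auscultation, SpO2, respiratory rate)
    scope: generic
    predicate:
      events:
        - {kind: task_completed, node: b_assess}
  - item_id: circulation_assessed
    description: Circulation assessed with shock class documented
    scope: generic
    predicate:
      events:
        - {kind: task_completed, node: circ_assess}
  - item_id: txa_administered
    description: Tranexamic acid given within the 3 h window
    scope: generic
    predicate:
      interventions:
        - {kind: txa}
      max_minutes_since_injury: 180
  - item_id: gcs_documented
    description: GCS components documented in the disability stage
    scope: generic
    predicate:
      events:
        - {kind: task_completed, node: d_assess}
  - item_id: full_body_exam
    description: Complete full-body examination performed
    scope: generic
    predicate:
      events:
        - {kind: task_completed, node: e_exam}
  - item_id: reevaluation_done
    description: At least one stage reevaluation performed
    scope: generic
    predicate:
      events_any:
        - {kind: task_completed, node: c_reeval}
        - {kind: task_completed, node: a_reeval}
        - {kind: task_completed, node: b_reeval}
        - {kind: task_completed, node: circ_reeval}
        - {kind: task_completed, node: d_reeval}
        - {kind: task_completed, node: e_reeval}

  # Case A: pneumothorax, bleeding scalp wound, splenic injury
  - item_id: chest_decompressed
    description: Tension pneumothorax decompressed (needle or chest tube)
    scope: scenario_specific
    applicable_scenarios: [A]
    predicate:
      interventions_any:
        - {kind: chest_decompression}
        - {kind: chest_tube}
  - item_id: scalp_hemostasis
    description: Scalp wound hemostasis by pressure dressing
    scope: scenario_specific
    applicable_scenarios: [A]
    predicate:
      interventions:
        - {kind: pressure_dressing, target: scalp}
  - item_id: splenic_bleeding_recognized
    description: Splenic bleeding recognized (FAST positive) with OR transfer decision
    scope: scenario_specific
    applicable_scenarios: [A]
    predicate:
      events:
        - {kind: task_completed, node: e_exam, payload: {free_abdominal_fluid: true}}
        - {kind: task_completed, node: transfer_decision, payload: {transfer_to: OR}}

  # Case B: severe TBI, unstable pelvis, free abdominal fluid
  - item_id: pelvic_binder_applied
    description: Unstable pelvis stabilized with a pelvic binder
    scope: scenario_specific
    applicable_scenarios: [B]
    predicate:
      interventions:
        - {kind: pelvic_binder}
  - item_id: head_ct_pathway
    description: Severe TBI pathway followed with immediate head CT decision
    scope: scenario_specific
    applicable_scenarios: [B]
    predicate:
      events:
        - {kind: task_completed, node: head_ct, payload: {performed: true}}
  - item_id: free_fluid_recognized
    description: Free abdominal fluid recognized during full-body examination
    scope: scenario_specific
    applicable_scenarios: [B]
    predicate:
      events:
        - {kind: task_completed, node: e_exam, payload: {free_abdominal_fluid: true}}
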