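# Ordered primary-survey stages of the main model.  Each stage is a
# signal-triggered region; re-throwing its signal re-runs the stage, and the
# reevaluation task is the region's loop entry point for repeats.
stages:
  - id: c
    name: critical bleeding
    signal: sig_c
    entry_task: c_assess
    reevaluation_task: c_reeval
  - id: A
    name: Airway
    signal: sig_a
    entry_task: a_assess
    reevaluation_task: a_reeval
  - id: B
    name: Breathing
    signal: sig_b
    entry_task: b_assess
    reevaluation_task: b_reeval
  - id: C
    name: Circulation
    signal: sig_circ
    entry_task: circ_assess
    reevaluation_task: circ_reeval
  - id: D
    name: Disability
    signal: sig_d
    entry_task: d_assess
    reevaluation_task: d_reeval
  - id: E
    name: Environment/Exposure
    signal: sig_e
    entry_task: e_exam
    reevaluation_task: e_reeval
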