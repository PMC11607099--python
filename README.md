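# resusflow

Workflow-based clinical decision support for resuscitation-room polytrauma
management — built for researchers and educators who study or run
simulation-based trauma training.

Severely injured patients are treated by a priority-ordered primary survey,
the **cABCDE scheme**: **c**ritical bleeding, **A**irway, **B**reathing,
**C**irculation, **D**isability, **E**nvironment/Exposure. resusflow makes
that algorithm executable and measurable:

* a **restricted BPMN 2.0 engine** that runs the treatment process
  token-wise — form-driven user tasks, XOR/AND gateways, signal-triggered
  stage regions with reevaluation loops, non-interrupting parallel
  subprocesses with variable inheritance and return, single-step back
  navigation, main/resuscitation timers, and a second-resolution audit log;
* **DMN-style decision tables** (hit policies UNIQUE and FIRST) plus the
  clinical calculators the workflow consults: Glasgow Coma Scale
  (eye + verbal + motor, 3–15), Injury Severity Score (sum of squares of the
  three highest worst-region AIS values; 75 if any AIS is 6), ATLS-style
  hemorrhagic shock class I–IV, and the tranexamic-acid rule (1000 mg when
  bleeding or shock ≥ II, within 3 h of injury);
* **bundled executable content**: the cABCDE main model, circulatory-shock
  and resuscitation subprocess models, five decision tables, and a 12-item
  essential-step rubric (9 generic + 3 scenario-specific items);
* a **deterministic virtual patient** for two training cases — case A:
  tension pneumothorax, bleeding scalp wound, splenic injury, class-III
  hemorrhagic shock; case B: severe traumatic brain injury, unstable pelvis,
  free abdominal fluid, class-III shock — whose vitals deteriorate under
  delayed treatment and respond to interventions;
* an **evaluation harness** that runs policy-driven sessions with or without
  decision support, scores them against the rubric, tallies interaction
  errors, compares arms with an exact Mann-Whitney U test, and renders
  handover / registry / training protocols.

## Worked example

```python
import resusflow as rf

content = rf.load_content()

# run the guideline-complete scripted session for case A, with support
policy = rf.Policy.scripted(content.scenarios["A"]["perfect_run"])
record = rf.run_session(content, "A", policy, assist=True, seed=1)
score = rf.score_session(record, rf.rubric_for(content, "A"))
tally = rf.tally_usage_errors(record)
print(f"score {score.total}/12, alive={record.alive}, duration={record.duration} s")
print("usage errors:", tally.total)

# a paired simulated experiment: error-prone policy with vs without support
records = rf.run_experiment(content, n_pairs=14, seed=7)
summary = rf.summarize_experiment(records, content)
print(f"without assist: {summary['without_assist']['score_mean']:.1f} "
      f"+/- {summary['without_assist']['score_sd']:.1f}")
print(f"with assist:    {summary['with_assist']['score_mean']:.1f} "
      f"+/- {summary['with_assist']['score_sd']:.1f}")
print(f"p = {summary['p_score']:.2g}")
```

prints

```
score 12/12, alive=True, duration=420 s
usage errors: 0
without assist: 7.6 +/- 1.7
with assist:    11.1 +/- 0.8
p = 9.2e-06
```

The perfect run completes every essential step (12/12) with the patient
alive and no interaction errors. In the paired experiment the same
error-prone policy scores higher with decision support because the engine
keeps presenting every required task — forgetting a step is replaced by the
weaker failure mode of refusing a presented one. The scores are simulation
outputs; they characterize the mechanics of the workflow support, not human
performance.

The same functionality is available from the shell:

```sh
resusflow validate src/resusflow/content
resusflow content list
resusflow decide txa_indication -i shock_class=III -i actively_bleeding=true \
    -i minutes_since_injury=90
resusflow simulate --scenario A --policy perfect --seed 1 --out session.json
resusflow score --session session.json
resusflow protocol --session session.json --type training --out report.md
resusflow experiment --n 14 --seed 7
```

`docs/methods.md` documents the execution semantics, the score definitions,
the virtual-patient dynamics and every tunable parameter.

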