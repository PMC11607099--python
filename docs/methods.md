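# Methods

This note documents the models, procedures and design choices behind
resusflow: what each component computes, which parameters matter, what the
simulated training sessions do and do not demonstrate, and where the design
was genuinely open.

## The workflow model and its execution semantics

All executable treatment content is expressed in a restricted BPMN 2.0
vocabulary: plain and signal-triggered start events, end events, user tasks
with typed form fields, business-rule tasks bound to decision tables,
service tasks bound to registered Python callables, exclusive (XOR) and
parallel (AND) gateways, signal throw events, call activities, and sequence
flows with optional guard conditions. Anything outside this subset is
rejected at parse time by name — parsing is total over the subset and never
silently drops an element (diagram-interchange elements and documentation
are the only ignored content). Task metadata that plain BPMN does not carry
(form fields, priority, intervention bindings, stability marks) lives in the
extension namespace `https://resusflow.dev/schema/bpmn-ext`, which this
package defines. Guard conditions use a deliberately small boolean grammar —
comparisons, `and`/`or`/`not`, set membership — rather than FEEL, so that
evaluation is deterministic and auditable.

Execution is token-based. The engine guarantees *quiescence*: after every
public operation, tokens rest only at user tasks, at a partially enabled AND
join, or are gone. XOR gateways evaluate their outgoing conditions in model
document order; the first satisfied flow wins and the default flow is taken
iff none is satisfied (an unsatisfiable gateway with no default is a routing
error). A guard over an absent variable simply evaluates to false. AND
gateways fork one token per outgoing flow and join by consuming one waiting
token per incoming flow.

The six primary-survey stages (c — critical bleeding, A — airway,
B — breathing, C — circulation, D — disability, E — environment/exposure)
are signal-triggered regions of the main model. A stage region stays
subscribed to its signal, so re-throwing it re-runs the stage; every stage
ends in a reevaluation task whose routing either repeats an earlier stage or
throws the next stage's signal. The circulatory-shock and resuscitation
subprocesses are separate models: the first is embedded in the C stage as a
non-interrupting call activity, and both can additionally be started at any
wait state through the engine's `start_parallel_subprocess` operation. A
child instance receives copies of the caller's variables and merges its
declared output variables back on completion. Starting the resuscitation
model also starts the dedicated resuscitation timer (declared on the model
via `rf:timerName`), alongside the main treatment timer that runs from
instance start.

Two interaction features deserve explicit semantics because they drive the
usage-error categories:

* **Back navigation.** A snapshot of (variables, token configuration,
  active tasks) is taken immediately before each user-task completion.
  `go_back` restores the most recent snapshot and consumes it. It is refused
  whenever tokens or child instances were created since the snapshot —
  restoring interleaved parallel state is ambiguous, so the contract is
  single-step linear undo only. The audit log is append-only: the
  restoration is logged; nothing is erased.
* **Contradictory-input guard.** Form fields may be marked *stable*
  (`stable="true"`): a submission that changes a stable variable, from a
  task not marked as reassessing it (`rf:reassesses`), re-presents the task
  once for confirmation before the value is accepted. Each stage's
  assessment task reassesses its own stable findings, so honest
  re-assessment after a stage re-run never trips the guard.

Time comes from an injected clock with integer-second resolution; the audit
log records every activation, completion, decision, gateway choice, signal,
subprocess event and back navigation with integer timestamps relative to
instance start. Identical inputs therefore produce byte-identical logs, and
replaying a log's task completions through a fresh instance reproduces the
final variable state.

## Decision tables and clinical scores

Decision tables are restricted DMN: typed inputs (optionally with declared
value domains), ordered rules whose condition cells are wildcards,
comparisons, intervals or enumerations, and a `UNIQUE` or `FIRST` hit
policy. `UNIQUE` demands exactly one match; zero or several is an error
surfaced to the caller, never resolved silently.

The bundled clinical logic:

* **GCS** = eye (1–4) + verbal (1–5) + motor (1–6), image exactly 3..15.
  The disability stage captures the components on a form; a service task
  computes the total, and a `UNIQUE` table bands it (3–8 severe, 9–12
  moderate, 13–15 mild) to gate the head-CT pathway.
* **ISS** uses the standard definition: worst AIS per body region, sum of
  squares of the three highest regions, 75 whenever any region is AIS 6.
* **Hemorrhagic shock class I–IV** is an ATLS-style staging encoded twice on
  purpose: as a Python function and as a `FIRST`-policy DMN table whose rows
  test one input band each (all class-IV rows first, then III, then II, then
  a wildcard row yielding I). Both compute the *worst* single-input band, so
  the class is monotone under any worsening input; band boundaries belong to
  the higher class. One deliberate banding choice: lethargy alone maps to
  class III rather than IV, so that depressed consciousness of neurological
  origin (severe TBI, as in case B) does not by itself force the worst
  hemorrhage class — only unresponsiveness does. The duplicated encodings
  cross-check each other in the tests.
* **Tranexamic acid**: indicated iff (actively bleeding or shock class ≥ II)
  and less than 180 min since injury; dose 1000 mg, otherwise 0.

The exact table cells are fixture content: they are tested for internal
consistency (full-grid agreement with rule-by-rule matching, equivalence
with the in-code classifier) rather than claimed as certified clinical
ground truth.

## The virtual patient

The simulator is a deterministic discrete-time system (default step 1 s)
whose whole purpose is *training-logic fidelity*: vitals deteriorate under
missing or delayed treatment and respond to interventions, with enough
structure that an early intervention schedule survives where the same
schedule applied late does not. It is explicitly not a physiological model:
no pharmacokinetics, no ventilation mechanics, no autonomic reflexes.

State: blood-volume fraction, HR, SBP, SpO2, RR, GCS, airway patency,
tension physiology, alive. Update rules, all declared in the scenario YAML:

* volume falls at the sum of uncontrolled bleed-source rates (fraction/min)
  and rises at the transfusion rate when a transfusion is running;
* HR, SBP and RR are memoryless piecewise-linear functions of the volume
  fraction (control points chosen so the declared initial vitals sit exactly
  on the maps);
* SpO2 falls at 0.05 %/s while tension physiology is undecompressed or the
  airway is unsecured, and otherwise recovers at 0.1 %/s (doubled under
  oxygen) toward a 97 % ceiling, floored at 60 %;
* GCS degrades by 1 point per 30 s while SBP is below the 70 mmHg
  cerebral-perfusion threshold, floored at 3;
* death freezes the state when SBP < 40 mmHg or the volume fraction < 0.5.

Interventions have declared effects: a pressure dressing zeroes its target
source; decompression or a chest tube clears tension physiology; a pelvic
binder multiplies the pelvic rate by 0.25; tranexamic acid multiplies all
rates by 0.7 when given within its 180 min window; transfusion adds
0.002/min; transfer to the OR controls every source (definitive care).
Application is idempotent per (kind, target), and a kind not applicable to
the scenario is rejected with the state unchanged — the session runner logs
it as a treatment error.

The two scenarios encode the training cases: case A (blunt assault) with a
left tension pneumothorax, a bleeding scalp wound (0.004/min, dressable) and
a splenic bleed (0.008/min, surgical control only), starting at volume
fraction 0.65; case B (6 m fall) with severe TBI (GCS 6, obstructed airway),
an unstable pelvis (0.006/min, binder-attenuable) and an abdominal bleed
(0.006/min), starting at 0.68. Both initial states classify as shock class
III, as the case definitions require; untreated death occurs at ~12.5 and
~15 min respectively, inside the intended 10–20 min band. Every numeric
vital, rate and map is a synthetic fixture parameter — labeled as such in
the files — constrained only by the case definitions, because the original
mannequin's dynamics are not public.

## Sessions, scoring and the simulated experiment

A session couples the engine (decision support on) or a memory-driven
action list (support off) to the simulator on one shared clock. Each trainee
action consumes 20 s of session time, a single fixed cost chosen to land
complete runs in a resuscitation-realistic 7–9 min; the simulator advances
second-by-second in between. Sessions end at the transfer decision, on
death, or when the policy is exhausted.

Policies replace the human participants. The scripted policy follows an
explicit action list (each scenario ships a "perfect run" script that
performs every guideline step — the fixture behind the 12/12 checks); the
guideline-adherent policy answers every presented form truthfully from
simulator ground truth; the error-prone policy omits steps and corrupts
answers with configured probabilities (defaults: adherence 0.9, omission
0.3 — free simulation knobs, deliberately not calibrated to any human
data). The asymmetry that produces the assist effect is structural, not
numeric: with decision support the engine enumerates every required task,
so the error-prone policy can only refuse a presented treatment, whereas
without support it must recall the guideline from memory — whole steps are
forgotten with the omission probability and the order drifts. Passing the
direction-of-effect check therefore shows that the workflow mechanics
convert forgetting into mere refusal; it says nothing about effect sizes in
humans, and the package makes no such claim.

Scoring is rubric-driven and declarative: 12 one-point items per scenario
(9 generic, 3 scenario-specific), each a pattern over the session record —
required events, required interventions (optionally with an
injury-to-intervention deadline), any-of alternatives, and an
order-adherence clause satisfied when completions of the six stage
assessments exist in non-decreasing time order (greedy subsequence match,
so adding actions can never lower a score). The usage-error tally counts
the observable interaction-error categories deterministically:
contradictory-input re-presentations, rejected submissions (operating
errors), back-button uses, interventions against or without the concurrently
recommended action, and documented values that contradict simulator ground
truth beyond per-vital tolerances (HR/SBP ±10, RR ±5, SpO2 ±4).

The rank-sum comparison between arms is a Mann-Whitney U with midrank tie
handling. For pooled sizes up to 20 the two-sided p-value is exact: the
doubled one-tail probability from full enumeration of all C(n,n₁) rank
assignments, capped at 1 — simple, auditable, and well-defined under ties.
Larger samples use the normal approximation with tie correction and
continuity correction. Arm summaries report mean ± sample standard
deviation (ddof 1; reported as 0 for singleton arms).

Three documents render deterministically from a completed record: a
prefilled handover summary, a structured trauma-registry field set (the
schema `resusflow-registry-1` is this package's own documented stand-in —
the official registry schema is proprietary), and a full training protocol
with rubric breakdown, usage errors and stage timings.

## Problem sizes and numerical choices

The verification harness uses exhaustive or closed-form oracles wherever
the state space allows: 500 randomly generated workflow models of at most 8
nodes checked against an independent token-game enumerator (structured
composition of sequence, binary AND and chooser-driven XOR blocks — cycles
without wait states are excluded by construction, and the engine
additionally guards against them with a step limit); full input grids for
every decision table, with numeric axes probed at every rule threshold ±1
and ±0.5; the complete 120-point GCS lattice; a 10,000-sample ISS sweep
against brute force; all Mann-Whitney size pairs with n₁+n₂ ≤ 10 against
enumeration; and 50 paired sessions for the direction-of-effect check.
These sizes keep the whole suite under half a minute on one CPU while
leaving no sampled gap in the small state spaces.

Floating-point choices: the simulator integrates volume with per-step
increments, so the untreated death time is checked against its closed form
with a ±2 s band rather than exact equality; decision cells compare numbers
exactly (thresholds are authored values, not computed ones); session files
round trace floats to fixed precision so that byte-identity is meaningful.

## Known limitations

The engine supports neither persistence across process restarts nor
multi-user interaction; back navigation is single-step and refuses to cross
concurrency; the condition grammar is not FEEL; the content is authored for
training-logic fidelity, not clinical certification; and the simulated
experiment quantifies the mechanics of decision support, not human
performance.
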