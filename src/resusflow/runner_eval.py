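"""Run, score and analyze complete training sessions.

A *session* couples the workflow engine (when decision support is on) or a
purely memory-driven action sequence (when it is off) to the virtual
patient.  Policies stand in for the human trainee:

* ``scripted`` — follows an explicit ordered action list (the scenarios ship
  a "perfect run" script that performs every guideline step);
* ``guideline_adherent`` — follows the scenario's canonical action list and
  answers every form truthfully from the simulator;
* ``error_prone`` — derives from the canonical list but omits steps, refuses
  treatments and corrupts assessment answers with configured probabilities.

With decision support the engine enumerates the required tasks, so an
error-prone trainee can only *refuse* a presented treatment; without it the
trainee must recall the guideline from memory, so whole steps are forgotten
and the order drifts.  That asymmetry — not any tuned constant — is what
makes assisted sessions score higher on average.

Scoring evaluates the declarative rubric predicates against the session's
audit events and applied interventions; the usage-error tally reproduces the
observable interaction-error categories (contradictory-input repetitions,
operating errors, back-button use, decisions against/without the active
recommendation, wrong parameter inputs).  ``mann_whitney_u`` provides the
rank-sum comparison used to contrast arms, with an exact enumerated p-value
at small sample sizes.
"""

from __future__ import annotations

import itertools
import json
import math
import random
import statistics
from dataclasses import dataclass, field, replace

from scipy.stats import norm, rankdata

from . import engine as _engine
from . import expressions
from . import patient_sim as _sim
from .clinical_content import ContentRegistry, rubric_for
from .engine import AuditEvent, SimClock
from .errors import FormValidationError, InapplicableInterventionError, ResusflowError
from .patient_sim import Intervention

ACTION_INTERVAL_S = 20  # wall-clock seconds consumed by one trainee action
MAX_SESSION_S = 3600

USAGE_ERROR_CATEGORIES = (
    "unnecessary_repetition",
    "operating_error",
    "back_button_use",
    "decision_against_recommendation",
    "decision_without_recommendation",
    "wrong_parameter_input",
)


@dataclass(frozen=True)
class Policy:
    kind: str  # scripted | guideline_adherent | error_prone
    script: tuple = ()
    adherence_prob: float = 1.0
    omission_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("scripted", "guideline_adherent", "error_prone"):
            raise ResusflowError(f"unknown policy kind {self.kind!r}")
        if not (0 <= self.adherence_prob <= 1 and 0 <= self.omission_prob <= 1):
            raise ResusflowError("policy probabilities must lie in [0, 1]")

    @staticmethod
    def scripted(actions) -> "Policy":
        return Policy(kind="scripted", script=tuple(_freeze(a) for a in actions))

    @staticmethod
    def guideline() -> "Policy":
        return Policy(kind="guideline_adherent")

    @staticmethod
    def error_prone(adherence_prob=0.9, omission_prob=0.3, seed=0) -> "Policy":
        return Policy(
            kind="error_prone",
            adherence_prob=adherence_prob,
            omission_prob=omission_prob,
            seed=seed,
        )


def _freeze(action: dict) -> tuple:
    return tuple(sorted((k, tuple(sorted(v.items())) if isinstance(v, dict) else v)
                        for k, v in action.items()))


def _thaw(frozen) -> dict:
    return {k: dict(v) if isinstance(v, tuple) and v and isinstance(v[0], tuple) else v
            for k, v in frozen}


@dataclass(frozen=True)
class InterventionRecord:
    kind: str
    target: str | None
    applied_at: int
    via_task: bool
    recommended_kinds: tuple  # intervention kinds of tasks active at that moment
    rejected: bool = False  # inapplicable to scenario (treatment error)


@dataclass
class SessionRecord:
    scenario_id: str
    assist: bool
    audit: list  # merged AuditEvent list on the session clock
    sim_trace: list  # one PatientState per simulated second
    interventions: list  # InterventionRecord, application order
    duration: int
    seed: int
    injury_time_offset_min: float
    rejected_submissions: list = field(default_factory=list)  # (t, node, reason)
    completed: bool = False

    @property
    def alive(self) -> bool:
        return self.sim_trace[-1].alive


@dataclass(frozen=True)
class SessionScore:
    items: tuple  # ((item_id, passed), ...) in rubric order
    total: int


@dataclass(frozen=True)
class UsageErrorTally:
    counts: tuple  # ((category, n), ...) in USAGE_ERROR_CATEGORIES order

    def __getitem__(self, category: str) -> int:
        return dict(self.counts)[category]

    @property
    def total(self) -> int:
        return sum(n for _, n in self.counts)


# ---------------------------------------------------------------------------
# Ground truth: what a diligent trainee would observe on the mannequin


def _decompose_gcs(total: int) -> tuple[int, int, int]:
    # canonical split: fill motor, then verbal, then eye
    rest = total - 3
    motor = 1 + min(5, rest)
    rest -= motor - 1
    verbal = 1 + min(4, rest)
    rest -= verbal - 1
    eye = 1 + rest
    return eye, verbal, motor


def truth_value(name: str, state, profile):
    """The simulator-ground-truth answer for one form field."""
    rates = _sim.effective_bleed_rates(profile, profile.applied)
    if name == "heart_rate":
        return round(state.heart_rate, 1)
    if name == "systolic_bp":
        return round(state.systolic_bp, 1)
    if name == "resp_rate":
        return round(state.resp_rate, 1)
    if name == "spo2":
        return round(state.spo2, 1)
    if name == "est_blood_loss_fraction":
        return round(1.0 - state.blood_volume_fraction, 2)
    if name == "mental_status":
        return _sim.mental_status_from_gcs(state.gcs)
    if name == "actively_bleeding":
        return any(r > 0 for r in rates.values())
    if name == "critical_bleeding":
        return any(
            rates[b.source] > 0 and "pressure_dressing" in b.controllable_by
            for b in profile.bleeds
        )
    if name == "bleeding_source":
        for b in profile.bleeds:
            if rates[b.source] > 0 and "pressure_dressing" in b.controllable_by:
                return b.source
        return "none"
    if name == "airway_patent":
        return state.airway_patent
    if name == "breath_sounds":
        if state.tension_physiology:
            side = (profile.thoracic_injury or {}).get("side", "left")
            return f"absent_{side}"
        return "normal"
    if name == "pelvis_unstable":
        return profile.pelvis_unstable
    if name == "free_abdominal_fluid":
        return profile.free_abdominal_fluid
    if name in ("gcs_eye", "gcs_verbal", "gcs_motor"):
        eye, verbal, motor = _decompose_gcs(int(state.gcs))
        return {"gcs_eye": eye, "gcs_verbal": verbal, "gcs_motor": motor}[name]
    raise ResusflowError(f"no ground truth for field {name!r}")


_TRUTH_FIELDS = (
    "heart_rate", "systolic_bp", "resp_rate", "spo2", "est_blood_loss_fraction",
    "mental_status", "actively_bleeding", "critical_bleeding", "bleeding_source",
    "airway_patent", "breath_sounds", "pelvis_unstable", "free_abdominal_fluid",
    "gcs_eye", "gcs_verbal", "gcs_motor",
)

_DEFAULT_ANSWERS = {
    "performed": True,
    "transfusion_started": True,
    "repeat_stage": "none",
    "transfer_to": "OR",
    "hypothermia_protection": True,
    "shockable": False,
    "rosc": True,
}

_TREATMENT_FIELDS = ("performed", "transfusion_started")


def _guideline_answers(task_node, state, profile, scenario_spec) -> dict:
    handover = {}
    for entry in scenario_spec.get("perfect_run", ()):
        if entry.get("task") == "handover":
            handover = entry.get("values", {})
    values = {}
    for f in task_node.form:
        if f.name in _TRUTH_FIELDS:
            values[f.name] = truth_value(f.name, state, profile)
        elif task_node.node_id == "handover" and f.name in handover:
            values[f.name] = handover[f.name]
        elif f.name in _DEFAULT_ANSWERS:
            values[f.name] = _DEFAULT_ANSWERS[f.name]
        elif f.required:
            values[f.name] = _declined_value(f)
    return values


def _declined_value(f):
    if f.value_type == "boolean":
        return False
    if f.value_type == "enum":
        return f.allowed_values[0]
    if f.value_type == "number":
        lo = f.range[0] if f.range and f.range[0] is not None else 0
        return lo
    return ""


def _declined_answers(task_node) -> dict:
    return {f.name: _declined_value(f) for f in task_node.form if f.required}


def _corrupt(values: dict, task_node, rng: random.Random) -> dict:
    """Perturb one assessment answer (a wrong parameter input)."""
    out = dict(values)
    names = [f.name for f in task_node.form if f.name in out and f.name in _TRUTH_FIELDS]
    if not names:
        return out
    name = rng.choice(names)
    v = out[name]
    fdef = next(f for f in task_node.form if f.name == name)
    if isinstance(v, bool):
        out[name] = not v
    elif isinstance(v, (int, float)):
        lo = fdef.range[0] if fdef.range and fdef.range[0] is not None else 0
        hi = fdef.range[1] if fdef.range and fdef.range[1] is not None else v + 30
        out[name] = max(lo, min(hi, v + rng.choice((-1, 1)) * 0.25 * (hi - lo or 1)))
    elif fdef.allowed_values:
        others = [a for a in fdef.allowed_values if a != v]
        if others:
            out[name] = rng.choice(others)
    return out


# ---------------------------------------------------------------------------
# Session execution


class _SessionDriver:
    def __init__(self, content: ContentRegistry, scenario_id: str, policy: Policy,
                 assist: bool, seed: int):
        if scenario_id not in content.scenarios:
            raise ResusflowError(f"unknown scenario {scenario_id!r}")
        self.content = content
        self.scenario_spec = content.scenarios[scenario_id]
        self.policy = policy
        self.assist = assist
        self.rng = random.Random((seed, policy.seed, scenario_id, assist).__repr__())
        self.clock = SimClock()
        self.state, self.profile = _sim.make_scenario(scenario_id, content.content_dir)
        self.sim_trace = [self.state]
        self.interventions: list[InterventionRecord] = []
        self.rejected: list = []
        self.passive_audit: list[AuditEvent] = []
        self.passive_vars: dict = {}
        self.completed = False
        self.record_seed = seed

        if policy.kind == "scripted":
            self.script = [_thaw(a) for a in policy.script]
        else:
            self.script = [dict(a) for a in self.scenario_spec["perfect_run"]]

    # -- time ------------------------------------------------------------

    def _advance_time(self, seconds: int) -> None:
        for _ in range(seconds):
            if not self.state.alive:
                return
            self.clock.advance(1)
            self.state = _sim.step(self.state, self.profile, self.profile.applied, 1)
            self.sim_trace.append(self.state)

    # -- interventions ---------------------------------------------------

    def _active_recommendations(self, instances) -> tuple:
        kinds = []
        for inst in instances:
            for task in inst.active_tasks:
                kind = task.node.ext_attr("intervention")
                if kind:
                    kinds.append(kind)
        return tuple(sorted(set(kinds)))

    def _apply_intervention(self, kind: str, target, via_task: bool, recommended: tuple):
        rec = InterventionRecord(
            kind=kind,
            target=target,
            applied_at=self.clock.now(),
            via_task=via_task,
            recommended_kinds=recommended,
        )
        try:
            iv = Intervention(kind=kind, applied_at=self.clock.now(), target=target)
            self.profile, self.state = _sim.apply_intervention(self.profile, self.state, iv)
        except InapplicableInterventionError:
            rec = replace(rec, rejected=True)
        self.interventions.append(rec)

    def _maybe_trigger_intervention(self, node, values: dict, scope: dict, recommended: tuple):
        kind = node.ext_attr("intervention")
        if not kind:
            return
        condition = node.ext_attr("interventionCondition")
        if condition:
            guard = expressions.parse_guard(condition)
            merged = {**scope, **values}
            if not expressions.evaluate_guard(guard, merged):
                return
        target = node.ext_attr("interventionTarget")
        target_var = node.ext_attr("interventionTargetVar")
        if target_var:
            target = {**scope, **values}.get(target_var)
            if target in (None, "none"):
                target = None
        self._apply_intervention(kind, target, via_task=True, recommended=recommended)

    # -- script matching -------------------------------------------------

    def _take_entry_for(self, node_id: str) -> dict | None:
        for i, entry in enumerate(self.script):
            if entry.get("task") == node_id:
                return self.script.pop(i)
        return None

    def _leading_direct_actions(self):
        while self.script and "task" not in self.script[0]:
            yield self.script.pop(0)

    def _resolve(self, values: dict) -> dict:
        return {
            k: truth_value(k, self.state, self.profile) if v == "$truth" else v
            for k, v in values.items()
        }

    # -- assisted sessions ------------------------------------------------

    def run_assisted(self) -> SessionRecord:
        registry = self.content.registry
        main = registry.workflow_models["cabcde_main"]
        root = _engine.start_instance(main, registry, {}, self.clock)
        steps = 0
        while self.state.alive and self.clock.now() < MAX_SESSION_S:
            steps += 1
            if steps > 500:
                break
            for action in self._leading_direct_actions():
                self._execute_direct(action, root)
            instances = [i for i in root.iter_instances() if i.status == "running"]
            tasks = [
                (inst, task)
                for inst in instances
                for task in _engine.list_active_tasks(inst)
            ]
            if not tasks:
                break
            tasks.sort(key=lambda it: (
                _engine._PRIORITY_RANK[it[1].priority], it[1].created_at, it[1].node.node_id
            ))
            inst, task = tasks[0]
            self._advance_time(ACTION_INTERVAL_S)
            if not self.state.alive:
                break
            values = self._answers_for(task.node)
            self._submit(inst, task, values)
        record = self._finish(root)
        return record

    def _answers_for(self, node) -> dict:
        if self.policy.kind == "scripted":
            entry = self._take_entry_for(node.node_id)
            if entry is None:
                return _declined_answers(node)
            return self._resolve(entry.get("values", {}))
        values = _guideline_answers(node, self.state, self.profile, self.scenario_spec)
        if self.policy.kind == "error_prone":
            treatment = [n for n in _TREATMENT_FIELDS if n in values]
            if treatment and self.rng.random() < self.policy.omission_prob:
                for n in treatment:
                    values[n] = False  # refuses the presented treatment
            if self.rng.random() > self.policy.adherence_prob:
                values = _corrupt(values, node, self.rng)
            if "transfer_to" in values and self.rng.random() > self.policy.adherence_prob:
                values["transfer_to"] = "CT"
        return values

    def _submit(self, inst, task, values: dict) -> None:
        recommended = self._active_recommendations(
            [i for i in inst.root().iter_instances() if i.status == "running"]
        )
        scope = dict(inst.variables)
        try:
            _engine.complete_task(inst, task.task_instance_id, values)
        except FormValidationError as exc:
            self.rejected.append((self.clock.now(), task.node.node_id, str(exc)))
            fallback = _guideline_answers(task.node, self.state, self.profile, self.scenario_spec)
            _engine.complete_task(inst, task.task_instance_id, fallback)
            values = fallback
        if any(t.task_instance_id == task.task_instance_id for t in inst.active_tasks):
            # contradictory-input guard: confirm once with the same values
            _engine.complete_task(inst, task.task_instance_id, values)
        if not any(t.task_instance_id == task.task_instance_id for t in inst.active_tasks):
            self._maybe_trigger_intervention(task.node, values, scope, recommended)

    def _execute_direct(self, action: dict, root) -> None:
        self._advance_time(ACTION_INTERVAL_S)
        if not self.state.alive:
            return
        if "intervention" in action:
            instances = [i for i in root.iter_instances() if i.status == "running"]
            recommended = self._active_recommendations(instances)
            self._apply_intervention(
                action["intervention"], action.get("target"), via_task=False,
                recommended=recommended,
            )
        elif "go_back" in action:
            _engine.go_back(root)
        elif "spawn" in action:
            _engine.start_parallel_subprocess(root, action["spawn"])

    def _finish(self, root) -> SessionRecord:
        merged: list[AuditEvent] = []
        for inst in root.iter_instances():
            offset = inst.start_time - root.start_time
            for e in inst.audit:
                merged.append(AuditEvent(e.timestamp + offset, e.kind, e.node_id, e.payload))
        merged.sort(key=lambda e: e.timestamp)
        self.completed = root.status == "completed"
        duration = merged[-1].timestamp if merged else 0
        return SessionRecord(
            scenario_id=self.scenario_spec["scenario_id"],
            assist=True,
            audit=merged,
            sim_trace=self.sim_trace,
            interventions=self.interventions,
            duration=duration,
            seed=self.record_seed,
            injury_time_offset_min=self.profile.injury_time_offset_min,
            rejected_submissions=self.rejected,
            completed=self.completed,
        )

    # -- unassisted sessions ----------------------------------------------

    def _memorized_actions(self) -> list[dict]:
        actions = [dict(a) for a in self.script]
        if self.policy.kind != "error_prone":
            return actions
        kept = [a for a in actions if self.rng.random() >= self.policy.omission_prob]
        # imperfect recall of the order: occasional adjacent swaps
        for i in range(len(kept) - 1):
            if self.rng.random() > self.policy.adherence_prob:
                kept[i], kept[i + 1] = kept[i + 1], kept[i]
        return kept

    def run_unassisted(self) -> SessionRecord:
        all_nodes = {}
        for model in self.content.registry.workflow_models.values():
            for node in model.nodes:
                all_nodes[node.node_id] = node
        self.passive_audit.append(AuditEvent(0, "instance_started", None, {"passive": True}))
        for action in self._memorized_actions():
            if not self.state.alive or self.clock.now() >= MAX_SESSION_S:
                break
            self._advance_time(ACTION_INTERVAL_S)
            if not self.state.alive:
                break
            if "task" not in action:
                if "intervention" in action:
                    self._apply_intervention(
                        action["intervention"], action.get("target"),
                        via_task=False, recommended=(),
                    )
                continue
            node = all_nodes.get(action["task"])
            if node is None:
                continue
            values = self._resolve(action.get("values", {}))
            if self.policy.kind == "error_prone" and self.rng.random() > self.policy.adherence_prob:
                values = _corrupt(values, node, self.rng)
            self.passive_vars.update(values)
            self.passive_audit.append(
                AuditEvent(self.clock.now(), "task_completed", node.node_id,
                           {"values": dict(values)})
            )
            self._maybe_trigger_intervention(node, values, self.passive_vars, ())
            if node.node_id == "transfer_decision":
                self.completed = True
                break
        duration = self.passive_audit[-1].timestamp if self.passive_audit else 0
        return SessionRecord(
            scenario_id=self.scenario_spec["scenario_id"],
            assist=False,
            audit=self.passive_audit,
            sim_trace=self.sim_trace,
            interventions=self.interventions,
            duration=duration,
            seed=self.record_seed,
            injury_time_offset_min=self.profile.injury_time_offset_min,
            rejected_submissions=self.rejected,
            completed=self.completed,
        )


def run_session(
    content: ContentRegistry,
    scenario_id: str,
    policy: Policy,
    assist: bool,
    seed: int = 0,
) -> SessionRecord:
    """Run one complete training session on the shared session clock.

    With ``assist`` the engine drives and the policy answers the presented
    tasks; without it the policy acts on the simulator from its own
    (possibly faulty) memory of the guideline, and only a passive event log
    is kept.  The session ends at the transfer decision, on patient death,
    or when the policy is exhausted.
    """
    driver = _SessionDriver(content, scenario_id, policy, assist, seed)
    return driver.run_assisted() if assist else driver.run_unassisted()


# ---------------------------------------------------------------------------
# Scoring


def _event_matches(event: AuditEvent, spec: dict) -> bool:
    if event.kind != spec.get("kind"):
        return False
    if "node" in spec and event.node_id != spec["node"]:
        return False
    if "payload" in spec:
        haystack = event.payload.get("values", event.payload) \
            if event.kind == "task_completed" else event.payload
        for key, expected in spec["payload"].items():
            if haystack.get(key) != expected:
                return False
    return True


def _intervention_matches(record: SessionRecord, spec: dict, deadline_min) -> bool:
    for iv in record.interventions:
        if iv.rejected or iv.kind != spec.get("kind"):
            continue
        if "target" in spec and iv.target != spec["target"]:
            continue
        if deadline_min is not None:
            minutes = record.injury_time_offset_min + iv.applied_at / 60.0
            if minutes >= deadline_min:
                continue
        return True
    return False


def _ordered_tasks_satisfied(record: SessionRecord, nodes: list) -> bool:
    t = -1
    for node in nodes:
        times = sorted(
            e.timestamp for e in record.audit
            if e.kind == "task_completed" and e.node_id == node and e.timestamp >= t
        )
        if not times:
            return False
        t = times[0]
    return True


def item_passes(record: SessionRecord, predicate: dict) -> bool:
    """Evaluate one declarative rubric predicate against a session record."""
    deadline = predicate.get("max_minutes_since_injury")
    for spec in predicate.get("events", ()):
        if not any(_event_matches(e, spec) for e in record.audit):
            return False
    if "events_any" in predicate:
        if not any(
            _event_matches(e, spec)
            for spec in predicate["events_any"]
            for e in record.audit
        ):
            return False
    for spec in predicate.get("interventions", ()):
        if not _intervention_matches(record, spec, deadline):
            return False
    if "interventions_any" in predicate:
        if not any(
            _intervention_matches(record, spec, deadline)
            for spec in predicate["interventions_any"]
        ):
            return False
    if "ordered_tasks" in predicate:
        if not _ordered_tasks_satisfied(record, predicate["ordered_tasks"]):
            return False
    return True


def score_session(record: SessionRecord, rubric_items) -> SessionScore:
    """One point per satisfied essential-step predicate; total 0-12."""
    applicable = [i for i in rubric_items if record.scenario_id in i.applicable_scenarios]
    if len(applicable) != len(rubric_items):
        raise ResusflowError("rubric items do not match the record's scenario")
    results = tuple(
        (item.item_id, item_passes(record, item.predicate)) for item in applicable
    )
    return SessionScore(items=results, total=sum(p for _, p in results))


# ---------------------------------------------------------------------------
# Usage errors


_TRUTH_TOLERANCES = {
    "heart_rate": 10.0,
    "systolic_bp": 10.0,
    "resp_rate": 5.0,
    "spo2": 4.0,
}
_TRUTH_BOOLEANS = (
    "airway_patent", "critical_bleeding", "pelvis_unstable", "free_abdominal_fluid",
)


def tally_usage_errors(record: SessionRecord) -> UsageErrorTally:
    """Deterministic per-category interaction-error counts (assisted only)."""
    if not record.assist:
        raise ResusflowError("usage-error categories reference active recommendations; "
                             "only assisted sessions can be tallied")
    by_t = {s.t: s for s in record.sim_trace}
    repetitions = sum(
        1 for e in record.audit
        if e.kind == "task_activated" and e.payload.get("reason") == "contradiction_confirmation"
    )
    back = sum(1 for e in record.audit if e.kind == "back_navigation")
    against = sum(
        1 for iv in record.interventions
        if not iv.via_task and iv.recommended_kinds and iv.kind not in iv.recommended_kinds
    )
    without = sum(
        1 for iv in record.interventions if not iv.via_task and not iv.recommended_kinds
    )
    wrong = 0
    for e in record.audit:
        if e.kind != "task_completed":
            continue
        state = by_t.get(e.timestamp)
        if state is None:
            continue
        values = e.payload.get("values", {})
        mismatch = False
        for name, tol in _TRUTH_TOLERANCES.items():
            if name in values and isinstance(values[name], (int, float)):
                truth = {"heart_rate": state.heart_rate, "systolic_bp": state.systolic_bp,
                         "resp_rate": state.resp_rate, "spo2": state.spo2}[name]
                if abs(values[name] - truth) > tol:
                    mismatch = True
        for name in _TRUTH_BOOLEANS:
            if name in values:
                truth = {"airway_patent": state.airway_patent,
                         "critical_bleeding": None, "pelvis_unstable": None,
                         "free_abdominal_fluid": None}[name]
                if truth is not None and values[name] != truth:
                    mismatch = True
        if mismatch:
            wrong += 1
    counts = (
        ("unnecessary_repetition", repetitions),
        ("operating_error", len(record.rejected_submissions)),
        ("back_button_use", back),
        ("decision_against_recommendation", against),
        ("decision_without_recommendation", without),
        ("wrong_parameter_input", wrong),
    )
    return UsageErrorTally(counts=counts)


# ---------------------------------------------------------------------------
# Statistics


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties and a two-sided p-value.

    For pooled sizes up to 20 the p-value is exact: the doubled one-tail
    probability from full enumeration of all C(n_a+n_b, n_a) rank
    assignments, capped at 1.  Larger samples use the normal approximation
    with tie correction and continuity correction.
    """
    a = list(sample_a)
    b = list(sample_b)
    if not a or not b:
        raise ResusflowError("both samples must be nonempty")
    n1, n2 = len(a), len(b)
    pooled = a + b
    ranks = rankdata(pooled)  # midranks
    u_stat = float(sum(ranks[:n1]) - n1 * (n1 + 1) / 2)

    if n1 + n2 <= 20:
        u_small = min(u_stat, n1 * n2 - u_stat)
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
            total += 1
            if u <= u_small + 1e-9:
                extreme += 1
        p = min(1.0, 2.0 * extreme / total)
        return u_stat, p

    mean = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = _tie_spectrum(pooled)
    tie_term = sum(t**3 - t for t in tie_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_stat, 1.0
    cc = 0.5 if u_stat != mean else 0.0
    z = (abs(u_stat - mean) - cc) / math.sqrt(var)
    return u_stat, min(1.0, 2.0 * float(norm.sf(z)))


def _tie_spectrum(values):
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return counts, [c for c in counts.values() if c > 1]


def summarize_experiment(records, content: ContentRegistry) -> dict:
    """Per-arm score/duration summaries plus between-arm rank-sum p-values."""
    arms = {True: [], False: []}
    for record in records:
        arms[record.assist].append(record)
    if not arms[True] or not arms[False]:
        raise ResusflowError("need at least one record per arm")

    def describe(recs):
        scores = [score_session(r, rubric_for(content, r.scenario_id)).total for r in recs]
        durations = [r.duration for r in recs]
        return {
            "n": len(recs),
            "score_mean": statistics.fmean(scores),
            "score_sd": statistics.stdev(scores) if len(scores) > 1 else 0.0,
            "duration_mean": statistics.fmean(durations),
            "duration_sd": statistics.stdev(durations) if len(durations) > 1 else 0.0,
            "scores": scores,
        }

    with_arm = describe(arms[True])
    without_arm = describe(arms[False])
    _, p_score = mann_whitney_u(without_arm.pop("scores"), with_arm.pop("scores"))
    _, p_duration = mann_whitney_u(
        [r.duration for r in arms[False]], [r.duration for r in arms[True]]
    )
    return {
        "with_assist": with_arm,
        "without_assist": without_arm,
        "p_score": p_score,
        "p_duration": p_duration,
        "score_mean_difference": with_arm["score_mean"] - without_arm["score_mean"],
    }


def run_experiment(
    content: ContentRegistry,
    n_pairs: int,
    seed: int,
    adherence_prob: float = 0.9,
    omission_prob: float = 0.3,
) -> list:
    """Paired error-prone sessions with and without decision support.

    Pair *i* uses the same policy seed in both arms and alternates between
    the two scenarios, emulating the study's crossed design."""
    records = []
    for i in range(n_pairs):
        scenario = "A" if i % 2 == 0 else "B"
        policy = Policy.error_prone(adherence_prob, omission_prob, seed=seed * 10_000 + i)
        records.append(run_session(content, scenario, policy, assist=False, seed=seed + i))
        records.append(run_session(content, scenario, policy, assist=True, seed=seed + i))
    return records


# ---------------------------------------------------------------------------
# Session serialization & protocols


def record_to_json(record: SessionRecord, score: SessionScore | None = None,
                   tally: UsageErrorTally | None = None) -> str:
    """Deterministic JSON for a session file (byte-identical across runs)."""
    doc = {
        "scenario_id": record.scenario_id,
        "assist": record.assist,
        "seed": record.seed,
        "duration": record.duration,
        "completed": record.completed,
        "alive": record.alive,
        "injury_time_offset_min": record.injury_time_offset_min,
        "audit": [
            {"timestamp": e.timestamp, "kind": e.kind, "node_id": e.node_id,
             "payload": e.payload}
            for e in record.audit
        ],
        "interventions": [
            {"kind": iv.kind, "target": iv.target, "applied_at": iv.applied_at,
             "via_task": iv.via_task, "recommended_kinds": list(iv.recommended_kinds),
             "rejected": iv.rejected}
            for iv in record.interventions
        ],
        "rejected_submissions": [list(r) for r in record.rejected_submissions],
        "sim_trace": [
            [s.t, round(s.heart_rate, 3), round(s.systolic_bp, 3), round(s.spo2, 3),
             round(s.resp_rate, 3), round(s.gcs, 3), round(s.blood_volume_fraction, 6),
             int(s.alive)]
            for s in record.sim_trace
        ],
    }
    if score is not None:
        doc["score"] = {"total": score.total, "items": dict(score.items)}
    if tally is not None:
        doc["usage_errors"] = dict(tally.counts)
    return json.dumps(doc, sort_keys=True, default=str)


@dataclass(frozen=True)
class ProtocolDocument:
    protocol_type: str
    markdown: str
    data: dict


def _stage_timings(record: SessionRecord) -> list:
    markers = {
        "c": ("c_assess", "c_reeval"), "A": ("a_assess", "a_reeval"),
        "B": ("b_assess", "b_reeval"), "C": ("circ_assess", "circ_reeval"),
        "D": ("d_assess", "d_reeval"), "E": ("e_exam", "e_reeval"),
    }
    rows = []
    for stage, (entry, reeval) in markers.items():
        starts = [e.timestamp for e in record.audit
                  if e.kind in ("task_activated", "task_completed") and e.node_id == entry]
        ends = [e.timestamp for e in record.audit
                if e.kind == "task_completed" and e.node_id == reeval]
        if starts:
            rows.append((stage, min(starts), max(ends) if ends else None))
    return rows


def generate_protocol(
    record: SessionRecord,
    score: SessionScore,
    tally: UsageErrorTally | None,
    protocol_type: str,
) -> ProtocolDocument:
    """Render one of the three end-of-session documents.

    ``handover``: prefilled patient/intervention summary for the next team.
    ``registry``: structured trauma-documentation field set (this package's
    documented stand-in schema).  ``training``: full timeline with rubric
    breakdown, usage errors and stage timings.  Rendering is deterministic.
    """
    if protocol_type not in ("handover", "registry", "training"):
        raise ResusflowError(f"unknown protocol type {protocol_type!r}")
    if not record.audit:
        raise ResusflowError("cannot render a protocol for an empty session")

    handover_values = {}
    for e in record.audit:
        if e.kind == "task_completed" and e.node_id == "handover":
            handover_values = e.payload.get("values", {})
    final = record.sim_trace[-1]
    iv_lines = [
        f"- t={iv.applied_at:>4d}s {iv.kind}" + (f" ({iv.target})" if iv.target else "")
        + (" [REJECTED: not applicable]" if iv.rejected else "")
        for iv in record.interventions
    ]

    if protocol_type == "handover":
        lines = [
            f"# Handover protocol — scenario {record.scenario_id}",
            "",
            f"Patient: {handover_values.get('gender', 'unknown')}, "
            f"mechanism: {handover_values.get('accident_type', 'unknown')}, "
            f"injury {record.injury_time_offset_min:.0f} min before arrival.",
            f"Session duration: {record.duration} s. "
            f"Outcome: {'alive' if record.alive else 'deceased'}, "
            f"{'transfer decided' if record.completed else 'no transfer decision'}.",
            "",
            "## Interventions",
            *(iv_lines or ["- none"]),
            "",
            "## Vitals at handover",
            f"HR {final.heart_rate:.0f}/min, SBP {final.systolic_bp:.0f} mmHg, "
            f"SpO2 {final.spo2:.0f}%, RR {final.resp_rate:.0f}/min, GCS {final.gcs:.0f}.",
        ]
        data = {
            "scenario": record.scenario_id,
            "patient": handover_values,
            "interventions": [
                {"t": iv.applied_at, "kind": iv.kind, "target": iv.target}
                for iv in record.interventions
            ],
            "outcome": {"alive": record.alive, "completed": record.completed},
        }
    elif protocol_type == "registry":
        data = {
            "schema": "resusflow-registry-1",
            "scenario": record.scenario_id,
            "gender": handover_values.get("gender"),
            "accident_type": handover_values.get("accident_type"),
            "prehospital_time_min": record.injury_time_offset_min,
            "resus_room_time_s": record.duration,
            "interventions": sorted({iv.kind for iv in record.interventions if not iv.rejected}),
            "final_vitals": {
                "heart_rate": round(final.heart_rate, 1),
                "systolic_bp": round(final.systolic_bp, 1),
                "spo2": round(final.spo2, 1),
                "resp_rate": round(final.resp_rate, 1),
                "gcs": round(final.gcs, 1),
            },
            "survived_resus_room": record.alive,
        }
        lines = [f"# Trauma-registry field set — scenario {record.scenario_id}", ""]
        lines += [f"- {k}: {json.dumps(v, sort_keys=True)}" for k, v in sorted(data.items())]
    else:  # training
        passed = [i for i, ok in score.items if ok]
        failed = [i for i, ok in score.items if not ok]
        lines = [
            f"# Training protocol — scenario {record.scenario_id} "
            f"({'with' if record.assist else 'without'} decision support)",
            "",
            f"Score: {score.total}/12 essential steps.",
            f"Passed: {', '.join(passed) or 'none'}.",
            f"Failed: {', '.join(failed) or 'none'}.",
            "",
            "## Usage errors",
        ]
        if tally is not None:
            lines += [f"- {cat}: {n}" for cat, n in tally.counts]
        else:
            lines += ["- not tallied (unassisted session)"]
        lines += ["", "## Stage timings"]
        for stage, start, end in _stage_timings(record):
            lines.append(
                f"- {stage}: entered t={start}s"
                + (f", reevaluated t={end}s" if end is not None else "")
            )
        lines += ["", "## Interventions", *(iv_lines or ["- none"]), "", "## Timeline"]
        for e in record.audit:
            if e.kind in ("task_completed", "decision_evaluated", "signal_thrown",
                          "subprocess_spawned", "back_navigation"):
                lines.append(f"- t={e.timestamp:>4d}s {e.kind} {e.node_id or ''}".rstrip())
        data = {
            "scenario": record.scenario_id,
            "assist": record.assist,
            "score": {"total": score.total, "items": dict(score.items)},
            "usage_errors": dict(tally.counts) if tally else None,
            "duration": record.duration,
        }
    return ProtocolDocument(protocol_type=protocol_type, markdown="\n".join(lines) + "\n",
                            data=data)
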