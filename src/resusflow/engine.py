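"""Token-based execution of process models.

A :class:`WorkflowInstance` holds the runtime state of one process model:
tokens, a typed variable scope, active user tasks, snapshots for
back-navigation, child instances spawned by call activities, named timers
and an append-only audit log with integer-second timestamps.

Execution semantics (deterministic by construction):

* After every public operation the instance is *quiescent* — tokens rest only
  at user tasks, at a partially-enabled AND join, at a blocking call
  activity, or are gone (completion).  Gateways, rule/service tasks and
  signal throws are traversed immediately.
* XOR gateways evaluate flow conditions in model document order; the first
  satisfied flow wins, the default flow is taken iff none is satisfied, and
  an unsatisfiable gateway raises :class:`RoutingError`.
* AND gateways fork one token per outgoing flow and join by consuming one
  waiting token per incoming flow.
* Thrown signals activate every signal-start region of the same model;
  regions stay subscribed, so re-throwing a stage signal re-runs the stage.
* Call activities spawn a child instance that inherits (copies of) the
  parent's variables; non-interrupting calls leave the parent running.  When
  the child completes, its declared output variables are merged back.
* Form submissions that contradict a previously captured *stable* variable
  (without the task being marked as reassessing it) re-present the task once
  for confirmation before the value is accepted — the contradictory-input
  guard.

Time comes from an injected clock with integer-second resolution, so
identical inputs yield byte-identical audit logs.
"""

from __future__ import annotations

import copy
import csv
import io
import json
from dataclasses import dataclass, field, replace

from .errors import (
    ConcurrencyError,
    FormValidationError,
    NoSnapshotError,
    ResusflowError,
    RoutingError,
    TimerNotStartedError,
    UnknownModelError,
    UnknownSignalError,
    UnknownTaskError,
)
from . import decisions as _decisions
from . import expressions
from .model_io import FlowNode, FormField, ProcessModel, Registry, validate

MAIN_TIMER = "main"

_PRIORITY_RANK = {"critical": 0, "high": 1, "normal": 2}

# Safety valve against models whose cycles contain no wait state.
_MAX_ADVANCE_STEPS = 100_000


class SimClock:
    """Injectable integer-second time source."""

    def __init__(self, start: int = 0):
        self._now = int(start)

    def now(self) -> int:
        return self._now

    def advance(self, seconds: int) -> None:
        if seconds < 0:
            raise ValueError("clock cannot run backwards")
        self._now += int(seconds)


@dataclass(frozen=True)
class Token:
    token_id: int
    node_id: str
    via_flow: str | None = None
    blocked_on_child: str | None = None  # child instance id for blocking calls


@dataclass(frozen=True)
class TaskInstance:
    task_instance_id: str
    node: FlowNode
    priority: str
    created_at: int
    form: tuple
    token_id: int


@dataclass(frozen=True)
class AuditEvent:
    timestamp: int
    kind: str
    node_id: str | None = None
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": self.timestamp,
                "kind": self.kind,
                "node_id": self.node_id,
                "payload": self.payload,
            },
            sort_keys=False,
            default=str,
        )


@dataclass(frozen=True)
class Snapshot:
    task_instance_id: str
    variables: dict
    tokens: tuple
    active_tasks: tuple
    tokens_created: int
    child_count: int


class WorkflowInstance:
    """Runtime state of one process model execution."""

    def __init__(self, model: ProcessModel, registry: Registry, clock: SimClock, parent=None):
        if parent is None:
            self._spawn_counter = 0
            self.instance_id = model.model_id
        else:
            root = parent.root()
            root._spawn_counter += 1
            self.instance_id = f"{model.model_id}-{root._spawn_counter}"
        self.model = model
        self.registry = registry
        self.clock = clock
        self.parent: WorkflowInstance | None = parent
        self.variables: dict = {}
        self.tokens: list[Token] = []
        self.active_tasks: list[TaskInstance] = []
        self.snapshots: list[Snapshot] = []
        self.children: list[WorkflowInstance] = []
        self.timers: dict[str, int] = {}
        self.status = "running"
        self.audit: list[AuditEvent] = []
        self.start_time = clock.now()
        self._token_counter = 0
        self._tokens_created = 0
        self._task_counter = 0
        self._pending_confirmation: set[str] = set()

    # -- helpers ----------------------------------------------------------

    def root(self) -> "WorkflowInstance":
        inst = self
        while inst.parent is not None:
            inst = inst.parent
        return inst

    def iter_instances(self):
        """This instance and all (transitive) children, parents first."""
        yield self
        for child in self.children:
            yield from child.iter_instances()

    def log(self, kind: str, node_id: str | None = None, **payload) -> None:
        ts = self.clock.now() - self.start_time
        if self.audit and ts < self.audit[-1].timestamp:  # pragma: no cover
            raise ResusflowError("audit timestamps must be non-decreasing")
        self.audit.append(AuditEvent(ts, kind, node_id, payload))

    def _new_token(self, node_id: str, via_flow: str | None = None) -> Token:
        self._token_counter += 1
        self._tokens_created += 1
        return Token(self._token_counter, node_id, via_flow)

    def _move(self, token: Token, flow) -> Token:
        moved = replace(token, node_id=flow.target, via_flow=flow.flow_id, blocked_on_child=None)
        self.tokens[self.tokens.index(token)] = moved
        return moved

    # -- advancing --------------------------------------------------------

    def _advance(self) -> None:
        steps = 0
        while True:
            token = self._next_processable()
            if token is None:
                break
            steps += 1
            if steps > _MAX_ADVANCE_STEPS:
                raise ResusflowError(
                    f"instance {self.instance_id} did not quiesce (task-free cycle?)"
                )
            self._process(token)
        if self.status == "running" and not self.tokens:
            self._complete()

    def _next_processable(self) -> Token | None:
        for token in self.tokens:
            node = self.model.node(token.node_id)
            if node.kind == "user_task":
                continue
            if token.blocked_on_child is not None:
                continue
            if node.kind == "and_gateway" and len(self.model.incoming(node.node_id)) > 1:
                if not self._join_ready(node):
                    continue
            return token
        return None

    def _join_ready(self, node: FlowNode) -> bool:
        waiting_flows = {
            t.via_flow for t in self.tokens if t.node_id == node.node_id
        }
        needed = {f.flow_id for f in self.model.incoming(node.node_id)}
        return needed <= waiting_flows

    def _fork(self, token: Token, flows) -> None:
        """Send the token along all given flows (first reuses the token)."""
        first, *rest = flows
        self._move(token, first)
        for flow in rest:
            self.tokens.append(self._new_token(flow.target, flow.flow_id))

    def _process(self, token: Token) -> None:
        node = self.model.node(token.node_id)
        out = self.model.outgoing(node.node_id)
        kind = node.kind

        if kind in ("start_event", "signal_catch_start"):
            self._fork(token, out)
        elif kind == "end_event":
            self.tokens.remove(token)
        elif kind == "xor_gateway":
            if len(out) == 1:
                chosen = out[0]
            else:
                chosen = None
                default = None
                for flow in out:
                    if flow.is_default:
                        default = flow
                        continue
                    if flow.condition is not None and expressions.evaluate_guard(
                        flow.condition, self.variables
                    ):
                        chosen = flow
                        break
                if chosen is None:
                    chosen = default
                if chosen is None:
                    raise RoutingError(
                        f"xor gateway {node.node_id!r}: no satisfiable flow and no default"
                    )
            self.log("gateway_taken", node.node_id, flow=chosen.flow_id)
            self._move(token, chosen)
        elif kind == "and_gateway":
            incoming = self.model.incoming(node.node_id)
            if len(incoming) > 1:
                # consume one waiting token per incoming flow, keep this one
                for flow in incoming:
                    if token.via_flow == flow.flow_id:
                        continue
                    for other in self.tokens:
                        if other is not token and other.node_id == node.node_id and other.via_flow == flow.flow_id:
                            self.tokens.remove(other)
                            break
            self.log("gateway_taken", node.node_id, flows=[f.flow_id for f in out])
            self._fork(token, out)
        elif kind == "business_rule_task":
            model = self.registry.decision_models.get(node.decision_ref)
            if model is None:
                raise UnknownModelError(f"decision {node.decision_ref!r} not in registry")
            inputs = {inp.name: self.variables.get(inp.name) for inp in model.inputs}
            result = _decisions.evaluate_decision(model, inputs)
            self.variables.update(result.outputs)
            self.log(
                "decision_evaluated",
                node.node_id,
                decision=node.decision_ref,
                rule_index=result.rule_index,
                outputs=result.outputs,
            )
            self._fork(token, out)
        elif kind == "service_task":
            handler = self.registry.services.get(node.service_ref)
            if handler is None:
                raise UnknownModelError(f"service {node.service_ref!r} not in registry")
            updates = handler(dict(self.variables)) or {}
            self.variables.update(updates)
            self.log("service_executed", node.node_id, service=node.service_ref, updates=updates)
            self._fork(token, out)
        elif kind == "signal_throw":
            self.log("signal_thrown", node.node_id, signal=node.signal_ref)
            self._trigger_catches(node.signal_ref)
            self._fork(token, out)
        elif kind == "call_activity":
            child = self._spawn_child(node.called_model_ref, inherit=None)
            self.log(
                "subprocess_spawned",
                node.node_id,
                model=node.called_model_ref,
                child_instance=child.instance_id,
                non_interrupting=node.non_interrupting,
            )
            if node.non_interrupting:
                self._fork(token, out)
            else:
                blocked = replace(token, blocked_on_child=child.instance_id)
                self.tokens[self.tokens.index(token)] = blocked
            child._advance()
        elif kind == "user_task":  # pragma: no cover - filtered before
            pass
        else:  # pragma: no cover
            raise ResusflowError(f"cannot process node kind {kind}")

        # Activate task instances for tokens newly resting at user tasks.
        self._activate_waiting_tasks()

    def _activate_waiting_tasks(self) -> None:
        tracked = {t.token_id for t in self.active_tasks}
        for token in self.tokens:
            node = self.model.node(token.node_id)
            if node.kind == "user_task" and token.token_id not in tracked:
                self._task_counter += 1
                task = TaskInstance(
                    task_instance_id=f"{node.node_id}#{self._task_counter}",
                    node=node,
                    priority=node.priority,
                    created_at=self.clock.now() - self.start_time,
                    form=node.form,
                    token_id=token.token_id,
                )
                self.active_tasks.append(task)
                self.log(
                    "task_activated",
                    node.node_id,
                    task_instance=task.task_instance_id,
                    priority=task.priority,
                )
                tracked.add(token.token_id)

    def _trigger_catches(self, signal_id: str) -> None:
        for node in self.model.nodes:
            if node.kind == "signal_catch_start" and node.signal_ref == signal_id:
                self.tokens.append(self._new_token(node.node_id))

    def _spawn_child(self, called_model_id: str, inherit) -> "WorkflowInstance":
        called = self.registry.workflow_models.get(called_model_id)
        if called is None:
            raise UnknownModelError(f"model {called_model_id!r} not in registry")
        child = WorkflowInstance(called, self.registry, self.clock, parent=self)
        names = inherit if inherit is not None else list(self.variables)
        child.variables = {k: copy.deepcopy(self.variables[k]) for k in names if k in self.variables}
        child.tokens.append(child._new_token(called.start_node_id))
        child.log("instance_started", called.start_node_id, model=called.model_id)
        if called.timer_name:
            root = self.root()
            root.timers.setdefault(called.timer_name, self.clock.now())
        self.children.append(child)
        return child

    def _complete(self) -> None:
        self.status = "completed"
        self.log("instance_completed")
        if self.parent is not None:
            outputs = {
                name: copy.deepcopy(self.variables[name])
                for name in self.model.output_variables
                if name in self.variables
            }
            self.parent.variables.update(outputs)
            self.parent.log(
                "subprocess_returned",
                None,
                model=self.model.model_id,
                child_instance=self.instance_id,
                outputs=outputs,
            )
            for name, value in outputs.items():
                self.parent.log("variable_set", None, name=name, value=value)
            # unblock any parent token waiting on this child
            for i, token in enumerate(self.parent.tokens):
                if token.blocked_on_child == self.instance_id:
                    node = self.parent.model.node(token.node_id)
                    flows = self.parent.model.outgoing(node.node_id)
                    self.parent.tokens[i] = replace(token, blocked_on_child=None)
                    self.parent._fork(self.parent.tokens[i], flows)
                    break
            self.parent._advance()


# ---------------------------------------------------------------------------
# Form validation


def _type_check_value(field_def: FormField, value) -> None:
    vt = field_def.value_type
    if vt == "number":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise FormValidationError(f"field {field_def.name!r} must be a number, got {value!r}")
        if field_def.range is not None:
            lo, hi = field_def.range
            if lo is not None and value < lo:
                raise FormValidationError(f"field {field_def.name!r}={value} below minimum {lo}")
            if hi is not None and value > hi:
                raise FormValidationError(f"field {field_def.name!r}={value} above maximum {hi}")
    elif vt == "boolean":
        if not isinstance(value, bool):
            raise FormValidationError(f"field {field_def.name!r} must be a boolean, got {value!r}")
    elif vt == "enum":
        if value not in field_def.allowed_values:
            raise FormValidationError(
                f"field {field_def.name!r} value {value!r} not in {field_def.allowed_values}"
            )
    elif vt in ("text", "datetime"):
        if not isinstance(value, str):
            raise FormValidationError(f"field {field_def.name!r} must be text, got {value!r}")


def validate_form_values(form: tuple, values: dict) -> None:
    declared = {f.name: f for f in form}
    for name in values:
        if name not in declared:
            raise FormValidationError(f"unexpected form field {name!r}")
    for field_def in form:
        if field_def.required and field_def.name not in values:
            raise FormValidationError(f"required field {field_def.name!r} missing")
        if field_def.name in values:
            _type_check_value(field_def, values[field_def.name])


# ---------------------------------------------------------------------------
# Public operations


def start_instance(
    model: ProcessModel,
    registry: Registry,
    initial_vars: dict | None = None,
    clock: SimClock | None = None,
) -> WorkflowInstance:
    """Start a validated model: one token at the start node, advanced until
    quiescence; the main treatment timer starts at t=0."""
    issues = validate(model, registry)
    if issues:
        raise ResusflowError("model has validation issues: " + "; ".join(map(str, issues)))
    clock = clock or SimClock()
    instance = WorkflowInstance(model, registry, clock)
    instance.variables = dict(initial_vars or {})
    instance.timers[MAIN_TIMER] = clock.now()
    instance.tokens.append(instance._new_token(model.start_node_id))
    instance.log("instance_started", model.start_node_id, model=model.model_id)
    instance._advance()
    instance._activate_waiting_tasks()
    return instance


def complete_task(instance: WorkflowInstance, task_instance_id: str, form_values: dict):
    """Submit a user task's form and advance to the next wait state.

    A submission that changes a *stable* variable without the task being
    marked as reassessing it re-presents the task once for confirmation (the
    contradictory-input guard); the repeated submission is then accepted.
    """
    task = next(
        (t for t in instance.active_tasks if t.task_instance_id == task_instance_id), None
    )
    if task is None:
        raise UnknownTaskError(f"no active task {task_instance_id!r}")
    validate_form_values(task.form, form_values)

    reassessed = set((task.node.ext_attr("reassesses") or "").split(","))
    contradictions = [
        f.name
        for f in task.form
        if f.stable
        and f.name in form_values
        and f.name in instance.variables
        and instance.variables[f.name] != form_values[f.name]
        and f.name not in reassessed
    ]
    if contradictions and task_instance_id not in instance._pending_confirmation:
        instance._pending_confirmation.add(task_instance_id)
        instance.log(
            "task_activated",
            task.node.node_id,
            task_instance=task_instance_id,
            priority=task.priority,
            reason="contradiction_confirmation",
            fields=sorted(contradictions),
        )
        return instance
    instance._pending_confirmation.discard(task_instance_id)

    instance.snapshots.append(
        Snapshot(
            task_instance_id=task_instance_id,
            variables=copy.deepcopy(instance.variables),
            tokens=tuple(instance.tokens),
            active_tasks=tuple(instance.active_tasks),
            tokens_created=instance._tokens_created,
            child_count=len(instance.children),
        )
    )

    instance.variables.update(form_values)
    instance.log(
        "task_completed",
        task.node.node_id,
        task_instance=task_instance_id,
        values=dict(form_values),
    )
    instance.active_tasks.remove(task)
    token = next(t for t in instance.tokens if t.token_id == task.token_id)
    flows = instance.model.outgoing(task.node.node_id)
    instance._fork(token, flows)
    instance._advance()
    instance._activate_waiting_tasks()
    return instance


def go_back(instance: WorkflowInstance):
    """Restore the state snapshot taken before the last task completion.

    Refused when tokens or child instances were created since the snapshot
    (back-navigation does not cross concurrency boundaries).  The audit log
    is append-only: the restoration itself is logged."""
    if not instance.snapshots:
        raise NoSnapshotError("no task completion to undo")
    snap = instance.snapshots[-1]
    if instance._tokens_created != snap.tokens_created or len(instance.children) != snap.child_count:
        raise ConcurrencyError("concurrent activity since the last snapshot; back refused")
    instance.snapshots.pop()
    instance.variables = copy.deepcopy(snap.variables)
    instance.tokens = list(snap.tokens)
    instance.active_tasks = list(snap.active_tasks)
    instance.status = "running"
    instance.log("back_navigation", None, restored_task=snap.task_instance_id)
    return instance


def throw_signal(instance: WorkflowInstance, signal_id: str):
    """Broadcast a signal: every subscribed signal-start region activates."""
    if signal_id not in instance.model.signals:
        raise UnknownSignalError(f"signal {signal_id!r} not declared in model")
    instance.log("signal_thrown", None, signal=signal_id)
    instance._trigger_catches(signal_id)
    instance.status = "running"
    instance._advance()
    instance._activate_waiting_tasks()
    return instance


def start_parallel_subprocess(
    instance: WorkflowInstance, called_model_id: str, inherit: list[str] | None = None
) -> WorkflowInstance:
    """Spawn a subprocess instance in parallel (the caller keeps running).

    The child receives copies of the inherited variables (all by default);
    on completion its declared output variables merge back into the caller."""
    child = instance._spawn_child(called_model_id, inherit)
    instance.log(
        "subprocess_spawned",
        None,
        model=called_model_id,
        child_instance=child.instance_id,
        non_interrupting=True,
    )
    child._advance()
    child._activate_waiting_tasks()
    return child


def list_active_tasks(instance: WorkflowInstance) -> list[TaskInstance]:
    """Active tasks in display order: critical first, then by age, then id."""
    return sorted(
        instance.active_tasks,
        key=lambda t: (_PRIORITY_RANK[t.priority], t.created_at, t.node.node_id),
    )


def elapsed(instance: WorkflowInstance, timer_name: str) -> int:
    """Integer seconds since the named timer (main / resuscitation) started."""
    timers = instance.root().timers
    if timer_name not in timers:
        raise TimerNotStartedError(f"timer {timer_name!r} was never started")
    return instance.clock.now() - timers[timer_name]


# ---------------------------------------------------------------------------
# Audit export & replay


def audit_to_jsonl(events: list[AuditEvent]) -> str:
    """One JSON object per line, stable field order."""
    return "\n".join(e.to_json() for e in events) + ("\n" if events else "")


def audit_to_csv(events: list[AuditEvent]) -> str:
    """CSV with flattened payload columns (sorted union of payload keys)."""
    keys = sorted({k for e in events for k in e.payload})
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["timestamp", "kind", "node_id"] + keys)
    for e in events:
        writer.writerow(
            [e.timestamp, e.kind, e.node_id or ""]
            + [json.dumps(e.payload[k], default=str) if k in e.payload else "" for k in keys]
        )
    return buf.getvalue()


def replay_audit(
    model: ProcessModel,
    registry: Registry,
    initial_vars: dict,
    events: list[AuditEvent],
) -> WorkflowInstance:
    """Re-execute the task completions of an audit log on a fresh instance.

    Replays single-instance logs (no call activities); used to check that an
    audit log fully determines the final variable state."""
    instance = start_instance(model, registry, initial_vars, SimClock())
    for event in events:
        if event.kind != "task_completed":
            continue
        task = next(
            (t for t in instance.active_tasks if t.node.node_id == event.node_id), None
        )
        if task is None:
            raise ResusflowError(f"replay: no active task at {event.node_id!r}")
        values = event.payload.get("values", {})
        complete_task(instance, task.task_instance_id, values)
        if any(t.task_instance_id == task.task_instance_id for t in instance.active_tasks):
            # contradictory-input guard re-presented the task: confirm
            complete_task(instance, task.task_instance_id, values)
    return instance
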