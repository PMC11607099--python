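"""Token execution semantics: routing, joins, signals, subprocesses,
back-navigation, timers and audit."""

import pytest

from resusflow.engine import (
    SimClock,
    audit_to_csv,
    audit_to_jsonl,
    complete_task,
    elapsed,
    go_back,
    list_active_tasks,
    replay_audit,
    start_instance,
    start_parallel_subprocess,
    throw_signal,
)
from resusflow.errors import (
    ConcurrencyError,
    FormValidationError,
    NoSnapshotError,
    RoutingError,
    TimerNotStartedError,
    UnknownSignalError,
    UnknownTaskError,
)
from resusflow.model_io import Registry, load_process_model

BPMN = "http://www.omg.org/spec/BPMN/20100524/MODEL"
EXT = "https://resusflow.dev/schema/bpmn-ext"


def wrap(body: str, model_id="p") -> str:
    return (f'<definitions xmlns="{BPMN}" xmlns:rf="{EXT}">'
            f'<process id="{model_id}">{body}</process></definitions>')


MINIMAL = wrap("""
  <startEvent id="s"/>
  <userTask id="t">
    <extensionElements><rf:formField name="x" type="number"/></extensionElements>
  </userTask>
  <endEvent id="e"/>
  <sequenceFlow id="f1" sourceRef="s" targetRef="t"/>
  <sequenceFlow id="f2" sourceRef="t" targetRef="e"/>
""")


def start_minimal():
    return start_instance(load_process_model(MINIMAL), Registry(), {}, SimClock())


def task_of(instance, node_id):
    return next(t for t in instance.active_tasks if t.node.node_id == node_id)


def test_start_reaches_first_wait_state():
    inst = start_minimal()
    assert [t.node.node_id for t in inst.active_tasks] == ["t"]
    assert inst.audit[0].kind == "instance_started"
    assert inst.audit[0].timestamp == 0


def test_completion_runs_to_end():
    inst = start_minimal()
    complete_task(inst, task_of(inst, "t").task_instance_id, {"x": 1})
    assert inst.status == "completed"
    assert inst.tokens == []
    assert inst.audit[-1].kind == "instance_completed"


AND_SPLIT = wrap("""
  <startEvent id="s"/>
  <parallelGateway id="split"/>
  <userTask id="p1"/><userTask id="q1"/>
  <parallelGateway id="join"/>
  <userTask id="r"/>
  <endEvent id="e"/>
  <sequenceFlow id="f1" sourceRef="s" targetRef="split"/>
  <sequenceFlow id="f2" sourceRef="split" targetRef="p1"/>
  <sequenceFlow id="f3" sourceRef="split" targetRef="q1"/>
  <sequenceFlow id="f4" sourceRef="p1" targetRef="join"/>
  <sequenceFlow id="f5" sourceRef="q1" targetRef="join"/>
  <sequenceFlow id="f6" sourceRef="join" targetRef="r"/>
  <sequenceFlow id="f7" sourceRef="r" targetRef="e"/>
""")


def test_and_split_fans_out_two_tasks():
    inst = start_instance(load_process_model(AND_SPLIT), Registry(), {}, SimClock())
    assert sorted(t.node.node_id for t in inst.active_tasks) == ["p1", "q1"]
    assert len(inst.tokens) == 2


def test_and_join_waits_for_all_branches():
    inst = start_instance(load_process_model(AND_SPLIT), Registry(), {}, SimClock())
    complete_task(inst, task_of(inst, "p1").task_instance_id, {})
    assert sorted(t.node.node_id for t in inst.active_tasks) == ["q1"]
    complete_task(inst, task_of(inst, "q1").task_instance_id, {})
    assert [t.node.node_id for t in inst.active_tasks] == ["r"]
    assert len(inst.tokens) == 1  # join merged the two branch tokens


XOR = wrap("""
  <startEvent id="s"/>
  <userTask id="ask">
    <extensionElements><rf:formField name="x" type="number" required="true"/></extensionElements>
  </userTask>
  <exclusiveGateway id="gw" default="fd"/>
  <userTask id="t1"/><userTask id="t2"/>
  <endEvent id="e"/>
  <sequenceFlow id="f1" sourceRef="s" targetRef="ask"/>
  <sequenceFlow id="f2" sourceRef="ask" targetRef="gw"/>
  <sequenceFlow id="fc" sourceRef="gw" targetRef="t1">
    <conditionExpression>x &gt; 5</conditionExpression>
  </sequenceFlow>
  <sequenceFlow id="fd" sourceRef="gw" targetRef="t2"/>
  <sequenceFlow id="f3" sourceRef="t1" targetRef="e"/>
  <sequenceFlow id="f4" sourceRef="t2" targetRef="e"/>
""")


@pytest.mark.parametrize("x,expected,flow", [(7, "t1", "fc"), (3, "t2", "fd")])
def test_xor_routes_by_condition_and_logs_choice(x, expected, flow):
    inst = start_instance(load_process_model(XOR), Registry(), {}, SimClock())
    complete_task(inst, task_of(inst, "ask").task_instance_id, {"x": x})
    assert [t.node.node_id for t in inst.active_tasks] == [expected]
    gateway_events = [e for e in inst.audit if e.kind == "gateway_taken"]
    assert gateway_events[-1].payload["flow"] == flow


def test_xor_without_satisfiable_flow_or_default_raises():
    doc = XOR.replace(' default="fd"', "").replace(
        '<sequenceFlow id="fd" sourceRef="gw" targetRef="t2"/>',
        '<sequenceFlow id="fd" sourceRef="gw" targetRef="t2">'
        "<conditionExpression>x &lt; 0</conditionExpression></sequenceFlow>",
    )
    inst = start_instance(load_process_model(doc), Registry(), {}, SimClock())
    with pytest.raises(RoutingError):
        complete_task(inst, task_of(inst, "ask").task_instance_id, {"x": 3})


# ---------------------------------------------------------------------------
# form validation


def test_form_validation_rejects_bad_submissions():
    inst = start_minimal()
    tid = task_of(inst, "t").task_instance_id
    with pytest.raises(FormValidationError):
        complete_task(inst, tid, {"x": "not a number"})
    with pytest.raises(FormValidationError):
        complete_task(inst, tid, {"unknown_field": 1})
    with pytest.raises(UnknownTaskError):
        complete_task(inst, "nope", {})


def test_required_and_range_constraints():
    doc = MINIMAL.replace('name="x" type="number"',
                          'name="x" type="number" required="true" min="0" max="10"')
    inst = start_instance(load_process_model(doc), Registry(), {}, SimClock())
    tid = task_of(inst, "t").task_instance_id
    with pytest.raises(FormValidationError):
        complete_task(inst, tid, {})
    with pytest.raises(FormValidationError):
        complete_task(inst, tid, {"x": 11})
    complete_task(inst, tid, {"x": 10})
    assert inst.status == "completed"


# ---------------------------------------------------------------------------
# contradictory-input guard


GUARD = wrap("""
  <startEvent id="s"/>
  <userTask id="t1">
    <extensionElements>
      <rf:formField name="airway_patent" type="boolean" stable="true"/>
    </extensionElements>
  </userTask>
  <userTask id="t2">
    <extensionElements>
      <rf:formField name="airway_patent" type="boolean" stable="true"/>
    </extensionElements>
  </userTask>
  <endEvent id="e"/>
  <sequenceFlow id="f1" sourceRef="s" targetRef="t1"/>
  <sequenceFlow id="f2" sourceRef="t1" targetRef="t2"/>
  <sequenceFlow id="f3" sourceRef="t2" targetRef="e"/>
""")


def test_contradictory_stable_value_represents_task_once():
    inst = start_instance(load_process_model(GUARD), Registry(), {}, SimClock())
    complete_task(inst, task_of(inst, "t1").task_instance_id, {"airway_patent": True})
    tid = task_of(inst, "t2").task_instance_id
    complete_task(inst, tid, {"airway_patent": False})  # contradiction: re-presented
    assert [t.task_instance_id for t in inst.active_tasks] == [tid]
    confirmations = [e for e in inst.audit
                     if e.payload.get("reason") == "contradiction_confirmation"]
    assert len(confirmations) == 1
    complete_task(inst, tid, {"airway_patent": False})  # confirmation accepted
    assert inst.status == "completed"
    assert inst.variables["airway_patent"] is False


def test_reassessing_task_changes_stable_value_without_guard():
    doc = GUARD.replace('<userTask id="t2">',
                        '<userTask id="t2" rf:reassesses="airway_patent">')
    inst = start_instance(load_process_model(doc), Registry(), {}, SimClock())
    complete_task(inst, task_of(inst, "t1").task_instance_id, {"airway_patent": True})
    complete_task(inst, task_of(inst, "t2").task_instance_id, {"airway_patent": False})
    assert inst.status == "completed"


# ---------------------------------------------------------------------------
# back navigation


def test_go_back_is_inverse_of_complete_task():
    inst = start_minimal()
    before = (dict(inst.variables), [t.node.node_id for t in inst.active_tasks])
    complete_task(inst, task_of(inst, "t").task_instance_id, {"x": 1})
    go_back(inst)
    assert "x" not in inst.variables
    assert (dict(inst.variables), [t.node.node_id for t in inst.active_tasks]) == before
    assert inst.audit[-1].kind == "back_navigation"


def test_double_go_back_restores_first_wait():
    inst = start_instance(load_process_model(GUARD), Registry(), {}, SimClock())
    complete_task(inst, task_of(inst, "t1").task_instance_id, {"airway_patent": True})
    complete_task(inst, task_of(inst, "t2").task_instance_id, {"airway_patent": True})
    go_back(inst)
    go_back(inst)
    assert [t.node.node_id for t in inst.active_tasks] == ["t1"]
    assert inst.variables == {}
    with pytest.raises(NoSnapshotError):
        go_back(inst)


def test_go_back_refused_across_concurrency(content):
    main = content.workflow_models["cabcde_main"]
    inst = start_instance(main, content.registry, {}, SimClock())
    complete_task(inst, task_of(inst, "handover").task_instance_id,
                  {"gender": "male", "accident_type": "blunt", "minutes_since_injury": 30})
    start_parallel_subprocess(inst, "resuscitation")
    with pytest.raises(ConcurrencyError):
        go_back(inst)


def test_go_back_refused_after_and_split():
    inst = start_instance(load_process_model(AND_SPLIT), Registry(), {}, SimClock())
    complete_task(inst, task_of(inst, "p1").task_instance_id, {})
    # completing p1 did not create tokens; completing q1 merges at the join
    complete_task(inst, task_of(inst, "q1").task_instance_id, {})
    go_back(inst)  # fine: no tokens were created since the last snapshot
    assert sorted(t.node.node_id for t in inst.active_tasks) == ["q1"]


# ---------------------------------------------------------------------------
# signals


def test_throwing_stage_signal_activates_stage(content):
    main = content.workflow_models["cabcde_main"]
    inst = start_instance(main, content.registry, {}, SimClock())
    throw_signal(inst, "sig_a")
    assert any(t.node.node_id == "a_assess" for t in inst.active_tasks)


def test_signal_without_subscriber_logged_without_state_change():
    doc = (f'<definitions xmlns="{BPMN}"><signal id="ghost"/>'
           '<process id="p"><startEvent id="s"/><userTask id="t"/><endEvent id="e"/>'
           '<sequenceFlow id="f1" sourceRef="s" targetRef="t"/>'
           '<sequenceFlow id="f2" sourceRef="t" targetRef="e"/>'
           "</process></definitions>")
    inst = start_instance(load_process_model(doc), Registry(), {}, SimClock())
    tasks_before = [t.task_instance_id for t in inst.active_tasks]
    throw_signal(inst, "ghost")
    assert [t.task_instance_id for t in inst.active_tasks] == tasks_before
    assert inst.audit[-1].kind == "signal_thrown"
    with pytest.raises(UnknownSignalError):
        throw_signal(inst, "undeclared")


def test_rethrowing_stage_signal_reruns_stage(content):
    main = content.workflow_models["cabcde_main"]
    inst = start_instance(main, content.registry, {}, SimClock())
    throw_signal(inst, "sig_a")
    complete_task(inst, task_of(inst, "a_assess").task_instance_id, {"airway_patent": True})
    complete_task(inst, task_of(inst, "a_reeval").task_instance_id, {"repeat_stage": "A"})
    # reevaluation chose to repeat the stage: the assessment is active again
    assert any(t.node.node_id == "a_assess" for t in inst.active_tasks)


# ---------------------------------------------------------------------------
# parallel subprocesses


def test_non_interrupting_spawn_leaves_parent_untouched(content):
    main = content.workflow_models["cabcde_main"]
    inst = start_instance(main, content.registry, {}, SimClock())
    before = [t.task_instance_id for t in inst.active_tasks]
    child = start_parallel_subprocess(inst, "resuscitation")
    assert [t.task_instance_id for t in inst.active_tasks] == before
    assert [t.node.node_id for t in child.active_tasks] == ["r_cpr"]


def test_child_outputs_merge_into_parent(content):
    main = content.workflow_models["cabcde_main"]
    inst = start_instance(main, content.registry, {}, SimClock())
    child = start_parallel_subprocess(inst, "resuscitation")
    complete_task(child, task_of(child, "r_cpr").task_instance_id, {"performed": True})
    complete_task(child, task_of(child, "r_rhythm").task_instance_id, {"shockable": False})
    complete_task(child, task_of(child, "r_rosc").task_instance_id, {"rosc": True})
    assert child.status == "completed"
    assert inst.variables["rosc"] is True
    kinds = [e.kind for e in inst.audit]
    assert "subprocess_returned" in kinds and "variable_set" in kinds


def test_two_children_merge_in_completion_order(content):
    main = content.workflow_models["cabcde_main"]
    inst = start_instance(main, content.registry, {}, SimClock())
    c1 = start_parallel_subprocess(inst, "circulatory_shock")
    c2 = start_parallel_subprocess(inst, "circulatory_shock")

    def finish(child, started):
        complete_task(child, task_of(child, "cs_access").task_instance_id, {"performed": True})
        complete_task(child, task_of(child, "cs_volume").task_instance_id,
                      {"transfusion_started": started})
        complete_task(child, task_of(child, "cs_labs").task_instance_id, {"performed": True})

    finish(c2, False)
    assert inst.variables["transfusion_started"] is False
    finish(c1, True)
    assert inst.variables["transfusion_started"] is True
    returns = [e for e in inst.audit if e.kind == "subprocess_returned"]
    assert [r.payload["child_instance"] for r in returns] == [c2.instance_id, c1.instance_id]


# ---------------------------------------------------------------------------
# ordering & timers


def test_active_tasks_ordered_by_priority_then_age(content):
    clock = SimClock()
    main = content.workflow_models["cabcde_main"]
    inst = start_instance(main, content.registry, {}, clock)  # handover (high) at t=0
    clock.advance(5)
    throw_signal(inst, "sig_e")  # e_exam (high) at t=5
    clock.advance(5)
    throw_signal(inst, "sig_c")  # c_assess (critical) at t=10
    ordered = list_active_tasks(inst)
    assert [t.node.node_id for t in ordered] == ["c_assess", "handover", "e_exam"]


def test_timers(content):
    clock = SimClock()
    main = content.workflow_models["cabcde_main"]
    inst = start_instance(main, content.registry, {}, clock)
    clock.advance(90)
    assert elapsed(inst, "main") == 90
    with pytest.raises(TimerNotStartedError):
        elapsed(inst, "resuscitation")
    clock.advance(10)  # spawn at t=100
    start_parallel_subprocess(inst, "resuscitation")
    clock.advance(20)
    assert elapsed(inst, "resuscitation") == 20
    assert elapsed(inst, "main") == 120


# ---------------------------------------------------------------------------
# audit determinism, export, replay


def _scripted_run():
    clock = SimClock()
    inst = start_instance(load_process_model(XOR), Registry(), {}, clock)
    clock.advance(30)
    complete_task(inst, task_of(inst, "ask").task_instance_id, {"x": 7})
    clock.advance(15)
    complete_task(inst, task_of(inst, "t1").task_instance_id, {})
    return inst


def test_identical_runs_give_byte_identical_audit_logs():
    log1 = audit_to_jsonl(_scripted_run().audit)
    log2 = audit_to_jsonl(_scripted_run().audit)
    assert log1 == log2
    csv1 = audit_to_csv(_scripted_run().audit)
    assert csv1 == audit_to_csv(_scripted_run().audit)
    assert csv1.splitlines()[0].startswith("timestamp,kind,node_id")


def test_audit_timestamps_non_decreasing_and_matched(content):
    inst = _scripted_run()
    times = [e.timestamp for e in inst.audit]
    assert times == sorted(times)
    activated = [e.payload.get("task_instance") for e in inst.audit
                 if e.kind == "task_activated"]
    completed = [e.payload.get("task_instance") for e in inst.audit
                 if e.kind == "task_completed"]
    assert set(completed) <= set(activated)


def test_replaying_audit_reproduces_final_variables():
    inst = _scripted_run()
    replayed = replay_audit(inst.model, Registry(), {}, inst.audit)
    assert replayed.variables == inst.variables
    assert replayed.status == inst.status


def test_quiescence_tokens_rest_only_at_user_tasks(content):
    main = content.workflow_models["cabcde_main"]
    inst = start_instance(main, content.registry, {}, SimClock())
    throw_signal(inst, "sig_d")
    for op in range(3):
        for token in inst.tokens:
            assert inst.model.node(token.node_id).kind == "user_task"
        if not inst.active_tasks:
            break
        task = list_active_tasks(inst)[0]
        values = {f.name: (3 if f.value_type == "number" else
                           f.allowed_values[0] if f.allowed_values else True)
                  for f in task.form}
        complete_task(inst, task.task_instance_id, values)
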