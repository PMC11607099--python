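"""Random small process models plus an independent token-game oracle.

The generator composes a start->blocks->end chain from three block shapes
(a plain user task, an AND split/join over two task branches, an XOR choice
over two task branches driven by an explicit chooser form field), keeping
the node count small enough for exhaustive exploration.

The oracle enumerates reachable quiescent task-markings directly on the
flow graph with nondeterministic XOR branching, entirely independent of the
engine's execution machinery.
"""

from __future__ import annotations

import itertools
import random

from resusflow import engine as eng
from resusflow.model_io import (
    FlowNode,
    FormField,
    ProcessModel,
    Registry,
    SequenceFlow,
)


def generate_model(rng: random.Random, max_nodes: int = 8) -> ProcessModel:
    nodes = [FlowNode("start", "start_event")]
    flows = []
    counter = itertools.count()
    budget = max_nodes - 2  # reserve start + end
    prev = "start"

    def link(src, dst, condition=None, default=False):
        flows.append(
            SequenceFlow(f"f{next(counter)}", src, dst, condition, default)
        )

    block_costs = {"task": 1, "and": 4, "xor": 5}
    while budget >= 1:
        options = [b for b, cost in block_costs.items() if cost <= budget]
        block = rng.choice(options)
        budget -= block_costs[block]
        n = next(counter)
        if block == "task":
            tid = f"t{n}"
            nodes.append(FlowNode(tid, "user_task"))
            link(prev, tid)
            prev = tid
        elif block == "and":
            split, join = f"andS{n}", f"andJ{n}"
            nodes.append(FlowNode(split, "and_gateway"))
            link(prev, split)
            for branch in ("p", "q"):
                tid = f"t{n}{branch}"
                nodes.append(FlowNode(tid, "user_task"))
                link(split, tid)
                link(tid, join)
            nodes.append(FlowNode(join, "and_gateway"))
            prev = join
        else:  # xor choice driven by an explicit chooser task
            from resusflow.expressions import parse_guard

            chooser = f"choose{n}"
            field = FormField(name=f"choice_{n}", value_type="enum",
                              allowed_values=("b0", "b1"), required=True)
            nodes.append(FlowNode(chooser, "user_task", form=(field,)))
            link(prev, chooser)
            gw, merge = f"xorS{n}", f"xorM{n}"
            nodes.append(FlowNode(gw, "xor_gateway"))
            link(chooser, gw)
            t0, t1 = f"t{n}b0", f"t{n}b1"
            nodes.append(FlowNode(t0, "user_task"))
            nodes.append(FlowNode(t1, "user_task"))
            link(gw, t0, parse_guard(f'choice_{n} == "b0"'))
            link(gw, t1, None, default=True)
            nodes.append(FlowNode(merge, "xor_gateway"))
            link(t0, merge)
            link(t1, merge)
            prev = merge
        if rng.random() < 0.3:
            break
    nodes.append(FlowNode("end", "end_event"))
    link(prev, "end")
    return ProcessModel(
        model_id="gen", name="generated", nodes=tuple(nodes), flows=tuple(flows),
        signals=(), start_node_id="start",
    )


# ---------------------------------------------------------------------------
# Independent token-game oracle


def _quiesce(model: ProcessModel, marking: tuple) -> set:
    """All quiescent markings reachable by propagating non-wait tokens.

    A marking is a sorted tuple of (node_id, via_flow) tokens; XOR gateways
    branch nondeterministically."""
    results = set()
    stack = [tuple(sorted(marking))]
    seen = set()
    while stack:
        m = stack.pop()
        if m in seen:
            continue
        seen.add(m)
        tokens = list(m)
        progressed = False
        for i, (node_id, via) in enumerate(tokens):
            node = model.node(node_id)
            rest = tokens[:i] + tokens[i + 1:]
            out = model.outgoing(node_id)
            if node.kind == "user_task":
                continue
            if node.kind == "end_event":
                stack.append(tuple(sorted(rest)))
                progressed = True
                break
            if node.kind == "xor_gateway":
                for flow in out:
                    stack.append(tuple(sorted(rest + [(flow.target, flow.flow_id)])))
                progressed = True
                break
            if node.kind == "and_gateway":
                incoming = model.incoming(node_id)
                if len(incoming) > 1:
                    here = [t for t in tokens if t[0] == node_id]
                    present = {t[1] for t in here}
                    if {f.flow_id for f in incoming} <= present:
                        remaining = list(tokens)
                        for flow in incoming:
                            remaining.remove((node_id, flow.flow_id))
                        for flow in out:
                            remaining.append((flow.target, flow.flow_id))
                        stack.append(tuple(sorted(remaining)))
                        progressed = True
                        break
                    continue  # partially enabled join: token waits
                stack.append(tuple(sorted(
                    rest + [(f.target, f.flow_id) for f in out]
                )))
                progressed = True
                break
            # start_event and anything else: fork along all outgoing flows
            stack.append(tuple(sorted(rest + [(f.target, f.flow_id) for f in out])))
            progressed = True
            break
        if not progressed:
            results.add(m)
    return results


def _task_marking(model: ProcessModel, marking: tuple) -> tuple:
    return tuple(sorted(
        node_id for node_id, _ in marking
        if model.node(node_id).kind == "user_task"
    ))


def oracle_task_markings(model: ProcessModel) -> set:
    """Every reachable quiescent task-marking, by brute-force enumeration."""
    seen_markings = set()
    task_markings = set()
    frontier = list(_quiesce(model, ((model.start_node_id, None),)))
    while frontier:
        m = frontier.pop()
        if m in seen_markings:
            continue
        seen_markings.add(m)
        task_markings.add(_task_marking(model, m))
        for i, (node_id, via) in enumerate(m):
            node = model.node(node_id)
            if node.kind != "user_task":
                continue
            rest = list(m[:i] + m[i + 1:])
            fired = rest + [(f.target, f.flow_id) for f in model.outgoing(node_id)]
            frontier.extend(_quiesce(model, tuple(sorted(fired))))
    return task_markings


# ---------------------------------------------------------------------------
# Engine-side exhaustive exploration


def _choices_for(node: FlowNode) -> list:
    for f in node.form:
        if f.value_type == "enum":
            return [{f.name: v} for f in (f,) for v in f.allowed_values]
    return [{}]


def engine_task_markings(model: ProcessModel) -> tuple[set, bool]:
    """Explore every completion order / choice via the engine itself.

    Returns (reachable task-markings, every leaf run completed)."""
    registry = Registry()
    markings = set()
    all_completed = True

    def replay(path):
        instance = eng.start_instance(model, registry, {}, eng.SimClock())
        for node_id, values in path:
            task = next(t for t in instance.active_tasks if t.node.node_id == node_id)
            eng.complete_task(instance, task.task_instance_id, values)
        return instance

    def explore(path):
        nonlocal all_completed
        instance = replay(path)
        marking = tuple(sorted(t.node.node_id for t in instance.active_tasks))
        markings.add(marking)
        if not instance.active_tasks:
            if instance.status != "completed":
                all_completed = False
            return
        for task in instance.active_tasks:
            for values in _choices_for(task.node):
                explore(path + [(task.node.node_id, values)])

    explore([])
    return markings, all_completed
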