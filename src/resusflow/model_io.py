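"""Parsing, validation and serialization of the restricted BPMN/DMN subset.

All executable content — the cABCDE main workflow, the circulatory-shock and
resuscitation subprocess models, and the decision tables they consult — is
carried in two restricted XML vocabularies:

* **BPMN 2.0 subset** (namespace ``http://www.omg.org/spec/BPMN/20100524/MODEL``):
  ``process``, ``startEvent`` (plain, or with ``signalEventDefinition`` as a
  signal-triggered region start), ``endEvent``, ``userTask``,
  ``businessRuleTask``, ``serviceTask``, ``exclusiveGateway``,
  ``parallelGateway``, ``intermediateThrowEvent`` + ``signalEventDefinition``,
  ``callActivity`` and ``sequenceFlow`` with an optional
  ``conditionExpression``.  Any other element raises
  :class:`~resusflow.errors.UnsupportedElementError`; BPMNDI diagram
  interchange and ``documentation`` elements are the only ignored content.

* **DMN subset**: a single ``decision`` holding one ``decisionTable`` with
  ``input``/``output`` declarations, ordered ``rule`` elements and a
  ``UNIQUE`` or ``FIRST`` hit policy.

Engine-relevant metadata that plain BPMN does not carry (form fields, task
priority, intervention bindings, stability marks) rides in the extension
namespace ``https://resusflow.dev/schema/bpmn-ext`` (prefix ``rf``), which is
fixed by this package and documented in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from lxml import etree

from . import expressions
from .errors import (
    ModelParseError,
    SerializationError,
    UnsupportedElementError,
)

BPMN_NS = "http://www.omg.org/spec/BPMN/20100524/MODEL"
EXT_NS = "https://resusflow.dev/schema/bpmn-ext"
DMN_NS = "https://www.omg.org/spec/DMN/20191111/MODEL/"

# BPMNDI / DC / DI diagram namespaces are ignored on input (no diagram
# interchange), everything else outside the subset raises.
_IGNORED_NS = (
    "http://www.omg.org/spec/BPMN/20100524/DI",
    "http://www.omg.org/spec/DD/20100524/DC",
    "http://www.omg.org/spec/DD/20100524/DI",
)

NODE_KINDS = (
    "start_event",
    "end_event",
    "user_task",
    "business_rule_task",
    "service_task",
    "xor_gateway",
    "and_gateway",
    "signal_throw",
    "signal_catch_start",
    "call_activity",
)

PRIORITIES = ("critical", "high", "normal")
VALUE_TYPES = ("number", "boolean", "enum", "text", "datetime")


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class FormField:
    name: str
    value_type: str = "text"
    allowed_values: tuple = ()
    required: bool = False
    range: tuple | None = None  # (min, max), either may be None
    stable: bool = False

    def __post_init__(self):
        if self.value_type not in VALUE_TYPES:
            raise ModelParseError(f"bad form field type {self.value_type!r}")
        if self.value_type == "enum" and not self.allowed_values:
            raise ModelParseError(f"enum field {self.name!r} needs allowed values")


@dataclass(frozen=True)
class FlowNode:
    node_id: str
    kind: str
    label: str = ""
    priority: str = "normal"
    form: tuple = ()
    decision_ref: str | None = None
    service_ref: str | None = None
    called_model_ref: str | None = None
    non_interrupting: bool = False
    signal_ref: str | None = None
    ext: tuple = ()  # sorted (key, value) extension attribute pairs

    def __post_init__(self):
        if self.kind not in NODE_KINDS:
            raise ModelParseError(f"bad node kind {self.kind!r}")
        if self.priority not in PRIORITIES:
            raise ModelParseError(f"bad priority {self.priority!r}")

    def ext_attr(self, key: str, default: str | None = None) -> str | None:
        for k, v in self.ext:
            if k == key:
                return v
        return default


@dataclass(frozen=True)
class SequenceFlow:
    flow_id: str
    source: str
    target: str
    condition: Any = None  # parsed guard AST
    is_default: bool = False


@dataclass(frozen=True)
class ProcessModel:
    model_id: str
    name: str
    nodes: tuple
    flows: tuple
    signals: tuple
    start_node_id: str
    output_variables: tuple = ()
    timer_name: str | None = None

    def node(self, node_id: str) -> FlowNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def outgoing(self, node_id: str) -> list[SequenceFlow]:
        return [f for f in self.flows if f.source == node_id]

    def incoming(self, node_id: str) -> list[SequenceFlow]:
        return [f for f in self.flows if f.target == node_id]


@dataclass(frozen=True)
class DecisionInput:
    name: str
    value_type: str  # number | boolean | string
    allowed_values: tuple = ()


@dataclass(frozen=True)
class DecisionOutput:
    name: str
    value_type: str


@dataclass(frozen=True)
class Rule:
    cells: tuple  # one expressions.Cell per input
    outputs: tuple  # one literal per output


@dataclass(frozen=True)
class DecisionModel:
    decision_id: str
    name: str
    inputs: tuple
    outputs: tuple
    rules: tuple
    hit_policy: str  # UNIQUE | FIRST


@dataclass(frozen=True)
class Issue:
    kind: str
    ref: str
    message: str

    def __str__(self):
        return f"{self.kind} [{self.ref}]: {self.message}"


@dataclass
class Registry:
    """Cross-model resolution context: all loadable models plus services."""

    workflow_models: dict = field(default_factory=dict)
    decision_models: dict = field(default_factory=dict)
    services: dict = field(default_factory=dict)  # name -> callable(vars)->updates


# ---------------------------------------------------------------------------
# BPMN parsing


def _to_root(document) -> etree._Element:
    if isinstance(document, etree._Element):
        return document
    is_path = isinstance(document, Path) or (
        isinstance(document, str) and not document.lstrip().startswith("<")
    )
    if is_path:
        try:
            return etree.parse(str(document)).getroot()
        except OSError as exc:
            raise ModelParseError(f"cannot read {document}: {exc}") from exc
        except etree.XMLSyntaxError as exc:
            raise ModelParseError(f"malformed XML in {document}: {exc}") from exc
    data = document.encode() if isinstance(document, str) else document
    try:
        return etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ModelParseError(f"malformed XML: {exc}") from exc


def _is_element(el) -> bool:
    # skip comments and processing instructions during child iteration
    return isinstance(el.tag, str)


def _tag(el) -> str:
    return etree.QName(el).localname


def _ns(el) -> str:
    return etree.QName(el).namespace or ""


def _req(el, attr: str) -> str:
    v = el.get(attr)
    if v is None:
        raise ModelParseError(f"<{_tag(el)}> missing required attribute {attr!r}")
    return v


def _parse_bool(text: str | None, default=False) -> bool:
    if text is None:
        return default
    return text.strip().lower() in ("true", "1", "yes")


def _parse_form_field(el) -> FormField:
    name = _req(el, "name")
    vt = el.get("type", "text")
    allowed = tuple(v.strip() for v in el.get("values", "").split(",") if v.strip())
    rng = None
    if el.get("min") is not None or el.get("max") is not None:
        lo = float(el.get("min")) if el.get("min") is not None else None
        hi = float(el.get("max")) if el.get("max") is not None else None
        rng = (lo, hi)
    return FormField(
        name=name,
        value_type=vt,
        allowed_values=allowed,
        required=_parse_bool(el.get("required")),
        range=rng,
        stable=_parse_bool(el.get("stable")),
    )


_EXT_NODE_ATTRS = (
    "reassesses",
    "intervention",
    "interventionTarget",
    "interventionTargetVar",
    "interventionCondition",
)


def _parse_flow_node(el, signal_ids: set[str]) -> FlowNode:
    tag = _tag(el)
    node_id = _req(el, "id")
    label = el.get("name", "")
    form: list[FormField] = []
    ext: list[tuple[str, str]] = []
    signal_ref = None

    for child in el:
        if not _is_element(child):
            continue
        ctag = _tag(child)
        cns = _ns(child)
        if cns in _IGNORED_NS or ctag == "documentation":
            continue
        if ctag in ("incoming", "outgoing"):
            continue  # redundant with sequenceFlow endpoints
        if ctag == "extensionElements":
            for ext_el in child:
                if not _is_element(ext_el):
                    continue
                if _ns(ext_el) != EXT_NS:
                    raise UnsupportedElementError(_tag(ext_el), node_id)
                if _tag(ext_el) == "formField":
                    form.append(_parse_form_field(ext_el))
                else:
                    raise UnsupportedElementError(_tag(ext_el), node_id)
            continue
        if ctag == "signalEventDefinition":
            signal_ref = _req(child, "signalRef")
            continue
        raise UnsupportedElementError(ctag, node_id)

    for attr in _EXT_NODE_ATTRS:
        v = el.get(f"{{{EXT_NS}}}{attr}")
        if v is not None:
            ext.append((attr, v))

    kind: str
    if tag == "startEvent":
        kind = "signal_catch_start" if signal_ref else "start_event"
    elif tag == "endEvent":
        kind = "end_event"
    elif tag == "userTask":
        kind = "user_task"
    elif tag == "businessRuleTask":
        kind = "business_rule_task"
    elif tag == "serviceTask":
        kind = "service_task"
    elif tag == "exclusiveGateway":
        kind = "xor_gateway"
    elif tag == "parallelGateway":
        kind = "and_gateway"
    elif tag == "intermediateThrowEvent":
        if not signal_ref:
            raise UnsupportedElementError(tag, node_id)
        kind = "signal_throw"
    elif tag == "callActivity":
        kind = "call_activity"
    else:  # pragma: no cover - guarded by caller
        raise UnsupportedElementError(tag, node_id)

    if signal_ref and signal_ref not in signal_ids:
        raise ModelParseError(f"node {node_id!r} references undeclared signal {signal_ref!r}")

    priority = el.get(f"{{{EXT_NS}}}priority", "normal")
    decision_ref = el.get(f"{{{EXT_NS}}}decisionRef") if kind == "business_rule_task" else None
    if kind == "business_rule_task" and decision_ref is None:
        raise ModelParseError(f"businessRuleTask {node_id!r} missing rf:decisionRef")
    service_ref = el.get(f"{{{EXT_NS}}}serviceRef") if kind == "service_task" else None
    if kind == "service_task" and service_ref is None:
        raise ModelParseError(f"serviceTask {node_id!r} missing rf:serviceRef")
    called = el.get("calledElement") if kind == "call_activity" else None
    if kind == "call_activity" and called is None:
        raise ModelParseError(f"callActivity {node_id!r} missing calledElement")

    return FlowNode(
        node_id=node_id,
        kind=kind,
        label=label,
        priority=priority if kind == "user_task" else "normal",
        form=tuple(form),
        decision_ref=decision_ref,
        service_ref=service_ref,
        called_model_ref=called,
        non_interrupting=_parse_bool(el.get(f"{{{EXT_NS}}}nonInterrupting"), True)
        if kind == "call_activity"
        else False,
        signal_ref=signal_ref,
        ext=tuple(sorted(ext)),
    )


def load_process_model(document) -> ProcessModel:
    """Parse a restricted-BPMN document into a :class:`ProcessModel`.

    ``document`` may be a filesystem path, an XML string/bytes, or a parsed
    element.  Unsupported BPMN elements raise
    :class:`UnsupportedElementError` naming the element; graph-level defects
    (dangling flows, unreachable nodes, ...) are left to :func:`validate`.
    """
    root = _to_root(document)
    if _tag(root) != "definitions" or _ns(root) != BPMN_NS:
        raise ModelParseError(f"expected BPMN <definitions>, got <{_tag(root)}>")

    signal_ids: set[str] = set()
    process_el = None
    for child in root:
        if not _is_element(child):
            continue
        ctag, cns = _tag(child), _ns(child)
        if cns in _IGNORED_NS or ctag == "documentation":
            continue
        if ctag == "signal":
            signal_ids.add(_req(child, "id"))
        elif ctag == "process":
            if process_el is not None:
                raise ModelParseError("multiple <process> elements; one per document")
            process_el = child
        else:
            raise UnsupportedElementError(ctag, "definitions")
    if process_el is None:
        raise ModelParseError("document contains no <process>")

    model_id = _req(process_el, "id")
    name = process_el.get("name", model_id)
    timer_name = process_el.get(f"{{{EXT_NS}}}timerName")

    nodes: list[FlowNode] = []
    flows: list[SequenceFlow] = []
    output_variables: list[str] = []
    default_flow_ids: set[str] = set()

    for child in process_el:
        if not _is_element(child):
            continue
        ctag, cns = _tag(child), _ns(child)
        if cns in _IGNORED_NS or ctag == "documentation":
            continue
        if ctag == "extensionElements":
            for ext_el in child:
                if not _is_element(ext_el):
                    continue
                if _ns(ext_el) == EXT_NS and _tag(ext_el) == "outputVariable":
                    output_variables.append(_req(ext_el, "name"))
                else:
                    raise UnsupportedElementError(_tag(ext_el), model_id)
            continue
        if ctag == "sequenceFlow":
            cond = None
            for fchild in child:
                if not _is_element(fchild):
                    continue
                if _tag(fchild) == "conditionExpression":
                    cond = expressions.parse_guard(fchild.text or "")
                elif _ns(fchild) in _IGNORED_NS or _tag(fchild) == "documentation":
                    continue
                else:
                    raise UnsupportedElementError(_tag(fchild), _req(child, "id"))
            flows.append(
                SequenceFlow(
                    flow_id=_req(child, "id"),
                    source=_req(child, "sourceRef"),
                    target=_req(child, "targetRef"),
                    condition=cond,
                )
            )
            continue
        node = _parse_flow_node(child, signal_ids)
        default = child.get("default")
        if default:
            default_flow_ids.add(default)
        nodes.append(node)

    if default_flow_ids:
        flows = [
            SequenceFlow(f.flow_id, f.source, f.target, f.condition, f.flow_id in default_flow_ids)
            for f in flows
        ]

    starts = [n for n in nodes if n.kind == "start_event"]
    if len(starts) != 1:
        raise ModelParseError(
            f"model {model_id!r} must have exactly one plain start event, found {len(starts)}"
        )

    return ProcessModel(
        model_id=model_id,
        name=name,
        nodes=tuple(nodes),
        flows=tuple(flows),
        signals=tuple(sorted(signal_ids)),
        start_node_id=starts[0].node_id,
        output_variables=tuple(output_variables),
        timer_name=timer_name,
    )


# ---------------------------------------------------------------------------
# Validation


def validate(model: ProcessModel, registry: Registry | None = None) -> list[Issue]:
    """Return all structural violations; an empty list means executable.

    With a ``registry``, call-activity / decision / service references are
    also resolved.  Issues are returned, never raised.
    """
    issues: list[Issue] = []
    node_ids = [n.node_id for n in model.nodes]
    seen: set[str] = set()
    for nid in node_ids:
        if nid in seen:
            issues.append(Issue("duplicate_id", nid, "duplicate node id"))
        seen.add(nid)
    flow_ids: set[str] = set()
    for f in model.flows:
        if f.flow_id in flow_ids:
            issues.append(Issue("duplicate_id", f.flow_id, "duplicate flow id"))
        flow_ids.add(f.flow_id)
        for endpoint in (f.source, f.target):
            if endpoint not in seen:
                issues.append(
                    Issue("dangling_flow", f.flow_id, f"endpoint {endpoint!r} is not a node")
                )

    # Reachability: plain start plus signal-triggered region starts are roots.
    adjacency: dict[str, list[str]] = {}
    for f in model.flows:
        adjacency.setdefault(f.source, []).append(f.target)
    roots = [model.start_node_id] + [
        n.node_id for n in model.nodes if n.kind == "signal_catch_start"
    ]
    reachable: set[str] = set()
    frontier = [r for r in roots if r in seen]
    while frontier:
        nid = frontier.pop()
        if nid in reachable:
            continue
        reachable.add(nid)
        frontier.extend(t for t in adjacency.get(nid, ()) if t in seen)
    for n in model.nodes:
        if n.node_id not in reachable:
            issues.append(Issue("unreachable_node", n.node_id, "not reachable from any start"))

    for n in model.nodes:
        out = model.outgoing(n.node_id)
        if n.kind != "end_event" and not out:
            issues.append(Issue("no_outgoing", n.node_id, "non-end node has no outgoing flow"))
        if n.kind == "end_event" and out:
            issues.append(Issue("end_with_outgoing", n.node_id, "end event has outgoing flow"))
        if n.kind == "xor_gateway" and len(out) > 1:
            if not any(f.condition is not None for f in out) and not any(
                f.is_default for f in out
            ):
                issues.append(
                    Issue(
                        "unguarded_xor",
                        n.node_id,
                        "xor gateway with >1 outgoing flow needs conditions or a default",
                    )
                )
            if sum(1 for f in out if f.is_default) > 1:
                issues.append(Issue("multiple_defaults", n.node_id, "more than one default flow"))
        if n.kind in ("signal_throw", "signal_catch_start") and n.signal_ref not in model.signals:
            issues.append(
                Issue("unknown_signal", n.node_id, f"signal {n.signal_ref!r} not declared")
            )
        if registry is not None:
            if n.kind == "call_activity" and n.called_model_ref not in registry.workflow_models:
                issues.append(
                    Issue(
                        "unresolved_reference",
                        n.node_id,
                        f"called model {n.called_model_ref!r} not in registry",
                    )
                )
            if n.kind == "business_rule_task" and n.decision_ref not in registry.decision_models:
                issues.append(
                    Issue(
                        "unresolved_reference",
                        n.node_id,
                        f"decision {n.decision_ref!r} not in registry",
                    )
                )
            if n.kind == "service_task" and n.service_ref not in registry.services:
                issues.append(
                    Issue(
                        "unresolved_reference",
                        n.node_id,
                        f"service {n.service_ref!r} not in registry",
                    )
                )
    return issues


# ---------------------------------------------------------------------------
# BPMN serialization


def serialize_process_model(model: ProcessModel, registry: Registry | None = None) -> bytes:
    """Emit the model as restricted-BPMN XML; inverse of :func:`load_process_model`.

    Raises :class:`SerializationError` when the model has validation issues
    (reference resolution is only checked when a registry is supplied).
    """
    issues = validate(model, registry)
    if issues:
        raise SerializationError("; ".join(str(i) for i in issues))

    nsmap = {None: BPMN_NS, "rf": EXT_NS}
    root = etree.Element(f"{{{BPMN_NS}}}definitions", nsmap=nsmap)
    root.set("targetNamespace", EXT_NS)
    for sig in model.signals:
        etree.SubElement(root, f"{{{BPMN_NS}}}signal", id=sig, name=sig)
    proc = etree.SubElement(root, f"{{{BPMN_NS}}}process", id=model.model_id, name=model.name)
    if model.timer_name:
        proc.set(f"{{{EXT_NS}}}timerName", model.timer_name)
    if model.output_variables:
        ext = etree.SubElement(proc, f"{{{BPMN_NS}}}extensionElements")
        for var in model.output_variables:
            etree.SubElement(ext, f"{{{EXT_NS}}}outputVariable", name=var)

    defaults: dict[str, str] = {}  # gateway node id -> default flow id
    for f in model.flows:
        if f.is_default:
            defaults[f.source] = f.flow_id

    tag_for = {
        "start_event": "startEvent",
        "signal_catch_start": "startEvent",
        "end_event": "endEvent",
        "user_task": "userTask",
        "business_rule_task": "businessRuleTask",
        "service_task": "serviceTask",
        "xor_gateway": "exclusiveGateway",
        "and_gateway": "parallelGateway",
        "signal_throw": "intermediateThrowEvent",
        "call_activity": "callActivity",
    }
    for n in model.nodes:
        el = etree.SubElement(proc, f"{{{BPMN_NS}}}{tag_for[n.kind]}", id=n.node_id)
        if n.label:
            el.set("name", n.label)
        if n.kind == "user_task" and n.priority != "normal":
            el.set(f"{{{EXT_NS}}}priority", n.priority)
        for key, value in n.ext:
            el.set(f"{{{EXT_NS}}}{key}", value)
        if n.kind == "business_rule_task":
            el.set(f"{{{EXT_NS}}}decisionRef", n.decision_ref)
        if n.kind == "service_task":
            el.set(f"{{{EXT_NS}}}serviceRef", n.service_ref)
        if n.kind == "call_activity":
            el.set("calledElement", n.called_model_ref)
            el.set(f"{{{EXT_NS}}}nonInterrupting", "true" if n.non_interrupting else "false")
        if n.node_id in defaults:
            el.set("default", defaults[n.node_id])
        if n.form:
            ext = etree.SubElement(el, f"{{{BPMN_NS}}}extensionElements")
            for ff in n.form:
                fel = etree.SubElement(ext, f"{{{EXT_NS}}}formField", name=ff.name, type=ff.value_type)
                if ff.allowed_values:
                    fel.set("values", ",".join(ff.allowed_values))
                if ff.required:
                    fel.set("required", "true")
                if ff.stable:
                    fel.set("stable", "true")
                if ff.range is not None:
                    lo, hi = ff.range
                    if lo is not None:
                        fel.set("min", expressions._fmt_number(lo))
                    if hi is not None:
                        fel.set("max", expressions._fmt_number(hi))
        if n.signal_ref:
            etree.SubElement(el, f"{{{BPMN_NS}}}signalEventDefinition", signalRef=n.signal_ref)

    for f in model.flows:
        fel = etree.SubElement(
            proc, f"{{{BPMN_NS}}}sequenceFlow", id=f.flow_id, sourceRef=f.source, targetRef=f.target
        )
        if f.condition is not None:
            cel = etree.SubElement(fel, f"{{{BPMN_NS}}}conditionExpression")
            cel.text = f.condition.unparse()

    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# DMN


_DMN_VALUE_TYPES = ("number", "boolean", "string")


def load_decision_model(document) -> DecisionModel:
    """Parse a restricted-DMN decision table into a :class:`DecisionModel`."""
    root = _to_root(document)
    if _tag(root) != "definitions" or _ns(root) != DMN_NS:
        raise ModelParseError(f"expected DMN <definitions>, got <{_tag(root)}>")
    decision_el = None
    for child in root:
        if not _is_element(child):
            continue
        if _tag(child) == "documentation":
            continue
        if _tag(child) != "decision":
            raise UnsupportedElementError(_tag(child), "definitions")
        if decision_el is not None:
            raise ModelParseError("multiple <decision> elements; one per document")
        decision_el = child
    if decision_el is None:
        raise ModelParseError("document contains no <decision>")
    decision_id = _req(decision_el, "id")
    name = decision_el.get("name", decision_id)

    table_el = None
    for child in decision_el:
        if not _is_element(child):
            continue
        if _tag(child) == "documentation":
            continue
        if _tag(child) != "decisionTable":
            raise UnsupportedElementError(_tag(child), decision_id)
        table_el = child
    if table_el is None:
        raise ModelParseError(f"decision {decision_id!r} has no <decisionTable>")

    hit_policy = table_el.get("hitPolicy", "UNIQUE")
    if hit_policy not in ("UNIQUE", "FIRST"):
        raise ModelParseError(f"unknown hit policy {hit_policy!r} in {decision_id!r}")

    inputs: list[DecisionInput] = []
    outputs: list[DecisionOutput] = []
    rules: list[Rule] = []
    for child in table_el:
        if not _is_element(child):
            continue
        ctag = _tag(child)
        if ctag == "documentation":
            continue
        if ctag == "input":
            expr_el = child.find(f"{{{DMN_NS}}}inputExpression")
            if expr_el is None:
                raise ModelParseError(f"input in {decision_id!r} lacks inputExpression")
            text_el = expr_el.find(f"{{{DMN_NS}}}text")
            input_name = (text_el.text or "").strip() if text_el is not None else ""
            if not input_name:
                raise ModelParseError(f"input in {decision_id!r} lacks a variable name")
            vt = expr_el.get("typeRef", "string")
            if vt not in _DMN_VALUE_TYPES:
                raise ModelParseError(f"bad input type {vt!r} in {decision_id!r}")
            allowed: tuple = ()
            values_el = child.find(f"{{{DMN_NS}}}inputValues")
            if values_el is not None:
                vtext_el = values_el.find(f"{{{DMN_NS}}}text")
                raw = (vtext_el.text or "") if vtext_el is not None else ""
                allowed = tuple(
                    expressions._parse_cell_literal(p) for p in raw.split(",") if p.strip()
                )
            inputs.append(DecisionInput(input_name, vt, allowed))
        elif ctag == "output":
            vt = child.get("typeRef", "string")
            if vt not in _DMN_VALUE_TYPES:
                raise ModelParseError(f"bad output type {vt!r} in {decision_id!r}")
            outputs.append(DecisionOutput(_req(child, "name"), vt))
        elif ctag == "rule":
            cells = []
            outs = []
            for entry in child:
                if not _is_element(entry):
                    continue
                etag = _tag(entry)
                text_el = entry.find(f"{{{DMN_NS}}}text")
                text = (text_el.text or "") if text_el is not None else ""
                if etag == "inputEntry":
                    cells.append(expressions.parse_cell(text))
                elif etag == "outputEntry":
                    outs.append(expressions.parse_output_literal(text))
                elif etag == "documentation":
                    continue
                else:
                    raise UnsupportedElementError(etag, decision_id)
            rules.append(Rule(tuple(cells), tuple(outs)))
        else:
            raise UnsupportedElementError(ctag, decision_id)

    for i, rule in enumerate(rules):
        if len(rule.cells) != len(inputs):
            raise ModelParseError(
                f"rule {i} of {decision_id!r} has {len(rule.cells)} condition cells "
                f"for {len(inputs)} inputs"
            )
        if len(rule.outputs) != len(outputs):
            raise ModelParseError(
                f"rule {i} of {decision_id!r} has {len(rule.outputs)} output entries "
                f"for {len(outputs)} outputs"
            )

    return DecisionModel(
        decision_id=decision_id,
        name=name,
        inputs=tuple(inputs),
        outputs=tuple(outputs),
        rules=tuple(rules),
        hit_policy=hit_policy,
    )


def serialize_decision_model(model: DecisionModel) -> bytes:
    """Emit the decision table as restricted-DMN XML."""
    nsmap = {None: DMN_NS}
    root = etree.Element(f"{{{DMN_NS}}}definitions", nsmap=nsmap)
    root.set("id", model.decision_id + "_def")
    root.set("name", model.name)
    dec = etree.SubElement(root, f"{{{DMN_NS}}}decision", id=model.decision_id, name=model.name)
    table = etree.SubElement(dec, f"{{{DMN_NS}}}decisionTable", hitPolicy=model.hit_policy)
    for inp in model.inputs:
        in_el = etree.SubElement(table, f"{{{DMN_NS}}}input", label=inp.name)
        expr = etree.SubElement(in_el, f"{{{DMN_NS}}}inputExpression", typeRef=inp.value_type)
        etree.SubElement(expr, f"{{{DMN_NS}}}text").text = inp.name
        if inp.allowed_values:
            values_el = etree.SubElement(in_el, f"{{{DMN_NS}}}inputValues")
            etree.SubElement(values_el, f"{{{DMN_NS}}}text").text = ", ".join(
                expressions._literal_text(v) for v in inp.allowed_values
            )
    for out in model.outputs:
        etree.SubElement(table, f"{{{DMN_NS}}}output", name=out.name, typeRef=out.value_type)
    for rule in model.rules:
        rule_el = etree.SubElement(table, f"{{{DMN_NS}}}rule")
        for cell in rule.cells:
            entry = etree.SubElement(rule_el, f"{{{DMN_NS}}}inputEntry")
            etree.SubElement(entry, f"{{{DMN_NS}}}text").text = cell.unparse()
        for value in rule.outputs:
            entry = etree.SubElement(rule_el, f"{{{DMN_NS}}}outputEntry")
            etree.SubElement(entry, f"{{{DMN_NS}}}text").text = expressions._literal_text(value)
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
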