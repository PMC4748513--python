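"""BPMN 2.0 interchange subset: data model, reader, writer, validation.

The subset is exactly what the guideline-relevant workflow patterns need:
tasks; exclusive/parallel/inclusive/event-based gateways; none and message
start events; intermediate message catch events; none and terminate end
events; ad hoc sub-processes; conditioned and default sequence flows.
Anything else in a document raises, never silently drops.

Two extension attributes (namespace ``urn:cigflow:bpmn-extension``, prefix
``cig``) form the dialect's pattern-annotation convention:

* ``cig:pattern`` on a region's entry node forces the pattern identity of
  that region (used for patterns whose pure control-flow shape is
  under-determined in BPMN: milestone, cancellation, critical section,
  interleaved parallel routing, discriminator/partial join, implicit
  termination);
* ``cig:persistent`` on an intermediate message event distinguishes a
  persistent trigger (``true``) from a transient one (``false``);
* ``cig:quorum`` on a split gateway gives the N of an N-out-of-M partial
  join.

Trigger associations (which task raises the signal an intermediate message
event waits for) are written as ``bpmn:association`` artifacts and accepted
on read either as associations or as ``bpmn:messageFlow`` elements of a
surrounding collaboration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import networkx as nx
from lxml import etree

from .errors import BpmnParseError, InvariantError, UnsupportedConstructError

BPMN_NS = "http://www.omg.org/spec/BPMN/20100524/MODEL"
EXT_NS = "urn:cigflow:bpmn-extension"
NSMAP = {"bpmn": BPMN_NS, "cig": EXT_NS}

NODE_KINDS = frozenset({
    "task", "exclusive_gateway", "parallel_gateway", "inclusive_gateway",
    "event_based_gateway", "start_event", "end_event", "start_message_event",
    "intermediate_message_event", "adhoc_subprocess", "terminate_end_event",
})
GATEWAY_KINDS = frozenset({
    "exclusive_gateway", "parallel_gateway", "inclusive_gateway", "event_based_gateway",
})
START_KINDS = frozenset({"start_event", "start_message_event"})
END_KINDS = frozenset({"end_event", "terminate_end_event"})
EVENT_KINDS = START_KINDS | END_KINDS | {"intermediate_message_event"}

_KIND_TO_TAG = {
    "task": "task",
    "exclusive_gateway": "exclusiveGateway",
    "parallel_gateway": "parallelGateway",
    "inclusive_gateway": "inclusiveGateway",
    "event_based_gateway": "eventBasedGateway",
    "adhoc_subprocess": "adHocSubProcess",
}
_GATEWAY_TAGS = {v: k for k, v in _KIND_TO_TAG.items() if v.endswith("Gateway")}


@dataclass(frozen=True)
class FlowNode:
    """A node of the process graph."""

    node_id: str
    kind: str
    name: Optional[str] = None
    # ad hoc sub-process only:
    children: tuple["FlowNode", ...] = ()
    ordering: Optional[str] = None            # "sequential" | "parallel"
    completion_condition: Optional[str] = None
    # dialect extension attributes:
    pattern_annotation: Optional[int] = None  # cig:pattern
    persistent: Optional[bool] = None         # cig:persistent (message events)
    quorum: Optional[int] = None              # cig:quorum (partial join)

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if (self.kind == "adhoc_subprocess") != bool(self.children):
            raise ValueError(
                f"node {self.node_id!r}: children are required for ad hoc "
                f"sub-processes and forbidden elsewhere"
            )


@dataclass(frozen=True)
class SequenceFlow:
    flow_id: str
    source: str
    target: str
    condition: Optional[str] = None
    is_default: bool = False


@dataclass(frozen=True)
class Trigger:
    """Association between an intermediate message event and the task raising it."""

    event: str   # node_id of the intermediate_message_event
    source: str  # node_id of the triggering task


@dataclass
class BpmnProcess:
    process_id: str
    nodes: list[FlowNode] = field(default_factory=list)
    flows: list[SequenceFlow] = field(default_factory=list)
    triggers: list[Trigger] = field(default_factory=list)

    # -- graph helpers ----------------------------------------------------

    def all_nodes(self) -> list[FlowNode]:
        """Top-level nodes plus ad hoc children, in document order."""
        out: list[FlowNode] = []
        for n in self.nodes:
            out.append(n)
            out.extend(n.children)
        return out

    def node(self, node_id: str) -> FlowNode:
        for n in self.all_nodes():
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def graph(self) -> nx.DiGraph:
        """Directed graph over top-level nodes and sequence flows."""
        top = {n.node_id for n in self.nodes}
        g = nx.DiGraph()
        g.add_nodes_from(top)
        for f in self.flows:
            if f.source in top and f.target in top:
                g.add_edge(f.source, f.target, flow=f)
        return g

    def outgoing(self, node_id: str) -> list[SequenceFlow]:
        return [f for f in self.flows if f.source == node_id]

    def incoming(self, node_id: str) -> list[SequenceFlow]:
        return [f for f in self.flows if f.target == node_id]

    def internal_flows(self, adhoc: FlowNode) -> list[SequenceFlow]:
        """Partial-order flows among the children of an ad hoc sub-process."""
        child_ids = {c.node_id for c in adhoc.children}
        return [f for f in self.flows if f.source in child_ids and f.target in child_ids]

    # -- invariants -------------------------------------------------------

    def problems(self) -> list[str]:
        """Invariant violations, empty when the process is well formed."""
        out: list[str] = []
        seen: set[str] = set()
        for n in self.all_nodes():
            if n.node_id in seen:
                out.append(f"duplicate node id {n.node_id!r}")
            seen.add(n.node_id)
        ids = seen
        child_ids = {c.node_id for n in self.nodes for c in n.children}
        for f in self.flows:
            if f.source not in ids or f.target not in ids:
                out.append(f"flow {f.flow_id!r} references unknown node")
                continue
            if f.source == f.target:
                out.append(f"flow {f.flow_id!r} is a self-loop")
            if f.is_default:
                src = self.node(f.source)
                if src.kind not in ("exclusive_gateway", "inclusive_gateway"):
                    out.append(
                        f"flow {f.flow_id!r} marked default but leaves a {src.kind}"
                    )
            in_adhoc = f.source in child_ids or f.target in child_ids
            if in_adhoc and not (f.source in child_ids and f.target in child_ids):
                out.append(f"flow {f.flow_id!r} crosses an ad hoc sub-process boundary")
        for t in self.triggers:
            if t.event not in ids or t.source not in ids:
                out.append("trigger association references unknown node")
            elif self.node(t.event).kind != "intermediate_message_event":
                out.append(f"trigger association target {t.event!r} is not a message event")
        g = self.graph()
        for comp in nx.weakly_connected_components(g):
            starts = [
                v for v in comp
                if self.node(v).kind in START_KINDS and g.in_degree(v) == 0
            ]
            if len(starts) != 1:
                out.append(
                    f"branch containing {sorted(comp)[0]!r} has {len(starts)} "
                    f"start events with no incoming flow (expected exactly 1)"
                )
        for n in self.nodes:
            if n.kind in END_KINDS and g.out_degree(n.node_id) != 0:
                out.append(f"end event {n.node_id!r} has outgoing flows")
        return out


@dataclass(frozen=True)
class StructurednessReport:
    structured: bool
    violations: tuple[tuple[str, str], ...]  # (node id, reason)


# ---------------------------------------------------------------------------
# reader


def _local(tag: str) -> str:
    return etree.QName(tag).localname


def _event_kind(elem, start: bool) -> str:
    defs = [c for c in elem if isinstance(c.tag, str) and _local(c.tag).endswith("EventDefinition")]
    if not defs:
        return "start_event" if start else "end_event"
    if len(defs) > 1:
        raise UnsupportedConstructError(_local(defs[1].tag))
    kind = _local(defs[0].tag)
    if kind == "messageEventDefinition" and start:
        return "start_message_event"
    if kind == "terminateEventDefinition" and not start:
        return "terminate_end_event"
    raise UnsupportedConstructError(kind)


def _ext_attrs(elem) -> dict:
    out = {}
    pat = elem.get(f"{{{EXT_NS}}}pattern")
    if pat is not None:
        out["pattern_annotation"] = int(pat)
    pers = elem.get(f"{{{EXT_NS}}}persistent")
    if pers is not None:
        out["persistent"] = pers.lower() == "true"
    quo = elem.get(f"{{{EXT_NS}}}quorum")
    if quo is not None:
        out["quorum"] = int(quo)
    return out


_IGNORED_LOCALS = {"documentation", "extensionElements", "incoming", "outgoing", "laneSet"}


def _parse_flow_elements(container, nodes: list, flows: list, assocs: list) -> None:
    for elem in container:
        if not isinstance(elem.tag, str):
            continue
        local = _local(elem.tag)
        if local in _IGNORED_LOCALS:
            continue
        nid = elem.get("id")
        name = elem.get("name")
        ext = _ext_attrs(elem)
        if local == "task":
            nodes.append(FlowNode(nid, "task", name, **ext))
        elif local in _GATEWAY_TAGS:
            nodes.append(FlowNode(nid, _GATEWAY_TAGS[local], name, **ext))
        elif local == "startEvent":
            nodes.append(FlowNode(nid, _event_kind(elem, start=True), name, **ext))
        elif local == "endEvent":
            nodes.append(FlowNode(nid, _event_kind(elem, start=False), name, **ext))
        elif local == "intermediateCatchEvent":
            defs = [c for c in elem if isinstance(c.tag, str)
                    and _local(c.tag).endswith("EventDefinition")]
            if len(defs) != 1 or _local(defs[0].tag) != "messageEventDefinition":
                raise UnsupportedConstructError(
                    _local(defs[0].tag) if defs else "intermediateCatchEvent"
                )
            nodes.append(FlowNode(nid, "intermediate_message_event", name, **ext))
        elif local == "adHocSubProcess":
            inner_nodes: list[FlowNode] = []
            _parse_flow_elements(
                [c for c in elem if isinstance(c.tag, str)
                 and _local(c.tag) != "completionCondition"],
                inner_nodes, flows, assocs,
            )
            cond_elem = elem.find(f"{{{BPMN_NS}}}completionCondition")
            cond = cond_elem.text if cond_elem is not None else None
            nodes.append(FlowNode(
                nid, "adhoc_subprocess", name,
                children=tuple(inner_nodes),
                ordering=elem.get("ordering", "parallel"),
                completion_condition=cond,
                **ext,
            ))
        elif local == "sequenceFlow":
            cond_elem = elem.find(f"{{{BPMN_NS}}}conditionExpression")
            cond = cond_elem.text if cond_elem is not None else None
            flows.append(SequenceFlow(nid, elem.get("sourceRef"), elem.get("targetRef"),
                                      condition=cond))
        elif local in ("association", "messageFlow"):
            assocs.append((elem.get("sourceRef"), elem.get("targetRef")))
        else:
            raise UnsupportedConstructError(local)


def parse_bpmn(document: str | bytes) -> BpmnProcess:
    """Read a BPMN 2.0 XML document into a :class:`BpmnProcess`.

    Raises :class:`BpmnParseError` on malformed XML (with the line number)
    and :class:`UnsupportedConstructError` for any element outside the
    supported subset.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise BpmnParseError(f"malformed XML: {exc}") from exc
    if _local(root.tag) != "definitions" or etree.QName(root.tag).namespace != BPMN_NS:
        raise BpmnParseError(
            "document root must be a 'definitions' element in the BPMN 2.0 namespace"
        )
    processes = root.findall(f"{{{BPMN_NS}}}process")
    if len(processes) != 1:
        raise BpmnParseError(f"expected exactly 1 process element, found {len(processes)}")
    proc_elem = processes[0]

    nodes: list[FlowNode] = []
    flows: list[SequenceFlow] = []
    assocs: list[tuple[str, str]] = []
    _parse_flow_elements(proc_elem, nodes, flows, assocs)
    # message flows of a surrounding collaboration are the alternative trigger
    # encoding (those inside the process were already collected)
    in_process = set(proc_elem.iter())
    for mf in root.iter(f"{{{BPMN_NS}}}messageFlow"):
        if mf not in in_process:
            assocs.append((mf.get("sourceRef"), mf.get("targetRef")))

    process = BpmnProcess(proc_elem.get("id") or "process", nodes, flows)
    by_id = {n.node_id: n for n in process.all_nodes()}
    # resolve default-flow references (attribute on the gateway)
    defaults = {
        elem.get("default")
        for elem in proc_elem.iter()
        if isinstance(elem.tag, str) and elem.get("default")
    }
    process.flows = [
        replace(f, is_default=True) if f.flow_id in defaults else f for f in flows
    ]
    for src, dst in assocs:
        ends = [by_id.get(src), by_id.get(dst)]
        if any(e is None for e in ends):
            raise BpmnParseError(f"association references unknown node ({src!r}, {dst!r})")
        events = [e for e in ends if e.kind == "intermediate_message_event"]
        others = [e for e in ends if e.kind != "intermediate_message_event"]
        if len(events) != 1:
            raise BpmnParseError(
                f"association ({src!r}, {dst!r}) must link a task to an "
                f"intermediate message event"
            )
        process.triggers.append(Trigger(event=events[0].node_id, source=others[0].node_id))

    problems = process.problems()
    if problems:
        raise BpmnParseError("; ".join(problems))
    return process


# ---------------------------------------------------------------------------
# writer


def _sub(parent, tag: str, **attrs):
    elem = etree.SubElement(parent, f"{{{BPMN_NS}}}{tag}")
    for key, value in attrs.items():
        if value is not None:
            elem.set(key, value)
    return elem


def _write_node(parent, node: FlowNode, defaults: dict[str, str]) -> None:
    ext = {}
    if node.pattern_annotation is not None:
        ext[f"{{{EXT_NS}}}pattern"] = str(node.pattern_annotation)
    if node.persistent is not None:
        ext[f"{{{EXT_NS}}}persistent"] = "true" if node.persistent else "false"
    if node.quorum is not None:
        ext[f"{{{EXT_NS}}}quorum"] = str(node.quorum)

    if node.kind in _KIND_TO_TAG and node.kind != "adhoc_subprocess":
        elem = _sub(parent, _KIND_TO_TAG[node.kind], id=node.node_id, name=node.name)
        if node.node_id in defaults:
            elem.set("default", defaults[node.node_id])
    elif node.kind in ("start_event", "start_message_event"):
        elem = _sub(parent, "startEvent", id=node.node_id, name=node.name)
        if node.kind == "start_message_event":
            _sub(elem, "messageEventDefinition")
    elif node.kind in ("end_event", "terminate_end_event"):
        elem = _sub(parent, "endEvent", id=node.node_id, name=node.name)
        if node.kind == "terminate_end_event":
            _sub(elem, "terminateEventDefinition")
    elif node.kind == "intermediate_message_event":
        elem = _sub(parent, "intermediateCatchEvent", id=node.node_id, name=node.name)
        _sub(elem, "messageEventDefinition")
    elif node.kind == "adhoc_subprocess":
        elem = _sub(parent, "adHocSubProcess", id=node.node_id, name=node.name,
                    ordering=node.ordering)
        if node.completion_condition is not None:
            _sub(elem, "completionCondition").text = node.completion_condition
        for child in node.children:
            _write_node(elem, child, defaults)
    else:  # pragma: no cover - kinds are validated on construction
        raise InvariantError(f"cannot serialize node kind {node.kind!r}")
    for key, value in ext.items():
        elem.set(key, value)


def serialize_bpmn(process: BpmnProcess) -> str:
    """Write a process back to BPMN 2.0 XML (deterministic, byte-stable).

    Refuses with :class:`InvariantError` when the process violates its
    invariants, so a round-trip is always graph-isomorphic.
    """
    problems = process.problems()
    if problems:
        raise InvariantError("; ".join(problems))
    root = etree.Element(f"{{{BPMN_NS}}}definitions", nsmap=NSMAP)
    root.set("targetNamespace", EXT_NS)
    proc = _sub(root, "process", id=process.process_id, isExecutable="false")
    defaults = {f.source: f.flow_id for f in process.flows if f.is_default}
    child_ids = {c.node_id for n in process.nodes for c in n.children}
    for node in process.nodes:
        _write_node(proc, node, defaults)
        if node.kind == "adhoc_subprocess":
            # internal partial-order flows are nested in the sub-process element
            adhoc_elem = proc[-1]
            for f in process.internal_flows(node):
                fe = _sub(adhoc_elem, "sequenceFlow", id=f.flow_id,
                          sourceRef=f.source, targetRef=f.target)
                if f.condition is not None:
                    _sub(fe, "conditionExpression").text = f.condition
    for f in process.flows:
        if f.source in child_ids:
            continue  # written inside the ad hoc sub-process
        fe = _sub(proc, "sequenceFlow", id=f.flow_id, sourceRef=f.source,
                  targetRef=f.target)
        if f.condition is not None:
            _sub(fe, "conditionExpression").text = f.condition
    for i, t in enumerate(process.triggers):
        _sub(proc, "association", id=f"{t.event}_assoc_{i}",
             sourceRef=t.source, targetRef=t.event)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# structuredness


def validate_structuredness(process: BpmnProcess) -> StructurednessReport:
    """Check that every split has a matching same-kind join and that
    split-join pairs nest properly (violations are reported, not raised)."""
    from .recognize import _parse_process  # local import to avoid a cycle

    _, violations = _parse_process(process)
    return StructurednessReport(structured=not violations, violations=tuple(violations))
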