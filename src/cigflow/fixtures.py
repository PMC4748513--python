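"""Deterministic canonical BPMN models for every guideline-relevant pattern.

One builder per relevant workflow pattern produces the pattern's canonical
BPMN 2.0 rendering; these models are the package's test corpus.  Node ids
derive from the pattern id and the node's role (``p4_xor_split``), so the
serialized XML is byte-stable across runs.

Canonical shapes (split/join pairs share one shape; the requested id only
changes the id prefix):

====  =====================================================================
id    shape
====  =====================================================================
1     start -> action_A -> action_B -> end
2/3   AND split -> one task per branch -> AND join
4/5   XOR split with mutually exclusive arc conditions -> tasks -> XOR join
6/7   OR split with independent arc conditions -> tasks -> OR join
9     shape of 2/3 with a discriminator annotation (quorum 1) on the split
11    shape of 1 with an implicit-termination annotation on the start event
16    event-based gateway -> message event + task per branch -> XOR merge
17    ad hoc sub-process (sequential) with an internal partial-order flow,
      annotated as interleaved parallel routing
18    shape of 1 annotated as milestone: action_A establishes the milestone
      that guards action_B
19    shape of 1 annotated as cancel activity (action_A is cancellable)
20    shape of 1 annotated as cancel case
21    post-test structured loop: XOR loop entry -> body -> XOR exit with a
      conditioned back edge
23/24 main branch start -> action_A -> message event -> action_B -> end,
      plus a triggering branch (message start -> trigger_action); the
      event/task trigger association carries the persistence flag
25    start -> action_A -> action_B -> action_C -> end annotated as cancel
      region over all but the last task
30    shape of 2/3 with 3 branches, annotated as partial join (quorum 2)
39    shape of 2/3 annotated as critical section
40    ad hoc sub-process with ordering "sequential" and a completion
      condition, one child task per branch
43    start -> action_A -> action_B -> terminate end event
====  =====================================================================
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from . import catalog
from .bpmn import BpmnProcess, FlowNode, SequenceFlow, Trigger, serialize_bpmn
from .errors import FixtureSpecError

#: schematic condition strings from the worked exclusive-choice example
XOR_CONDITION = 'condition="yes"'
XOR_CONDITION_NEG = 'not (condition="yes")'

#: the interchange dialect's reading of an ad hoc completion condition; an
#: approximation in that it relies on the performer activating each
#: contained activity exactly once
ADHOC_COMPLETION = "all contained activities completed exactly once"

_BRANCHING = frozenset({2, 3, 4, 5, 6, 7, 9, 16, 17, 30, 39, 40})


@dataclass(frozen=True)
class FixtureSpec:
    pattern_id: int
    branch_count: Optional[int] = None
    task_names: Optional[Sequence[str]] = None
    seed: int = 0

    def resolved_branches(self) -> int:
        if self.branch_count is not None:
            return self.branch_count
        return 3 if self.pattern_id in (17, 30, 40) else 2


def _names(spec: FixtureSpec, count: int) -> list[str]:
    if spec.task_names is not None:
        if len(spec.task_names) < count:
            raise FixtureSpecError(
                f"pattern #{spec.pattern_id} needs {count} task names, "
                f"got {len(spec.task_names)}"
            )
        return list(spec.task_names[:count])
    return [f"action_{letter}" for letter in string.ascii_uppercase[:count]]


class _Builder:
    def __init__(self, prefix: str) -> None:
        self.prefix = prefix
        self.nodes: list[FlowNode] = []
        self.flows: list[SequenceFlow] = []
        self.triggers: list[Trigger] = []
        self._flow_n = 0

    def nid(self, role: str) -> str:
        return f"{self.prefix}_{role}"

    def add(self, role: str, kind: str, name: Optional[str] = None, **kw) -> str:
        node_id = self.nid(role)
        self.nodes.append(FlowNode(node_id, kind, name, **kw))
        return node_id

    def flow(self, source: str, target: str, condition: Optional[str] = None,
             is_default: bool = False) -> None:
        self._flow_n += 1
        self.flows.append(SequenceFlow(f"{self.prefix}_f{self._flow_n}",
                                       source, target, condition, is_default))

    def chain(self, *node_ids: str) -> None:
        for a, b in zip(node_ids, node_ids[1:]):
            self.flow(a, b)

    def process(self, pid: str) -> BpmnProcess:
        return BpmnProcess(pid, self.nodes, self.flows, self.triggers)


def generate_fixture(spec: FixtureSpec) -> BpmnProcess:
    """Build the canonical structured model for ``spec.pattern_id``."""
    descriptor = catalog.get_pattern(spec.pattern_id)
    if not descriptor.relevant:
        raise FixtureSpecError(
            f"pattern #{spec.pattern_id} ({descriptor.name}) is not relevant to "
            f"the guideline domain; no fixture exists"
        )
    k = spec.resolved_branches()
    if spec.pattern_id in _BRANCHING and k < 2:
        raise FixtureSpecError(
            f"pattern #{spec.pattern_id} requires branch_count >= 2, got {k}"
        )
    pid = spec.pattern_id
    b = _Builder(f"p{pid}")
    builder = _SHAPES[pid]
    builder(b, spec)
    return b.process(f"fixture_p{pid}")


def fixture_xml(spec: FixtureSpec) -> str:
    """Byte-stable BPMN 2.0 XML for a fixture."""
    return serialize_bpmn(generate_fixture(spec))


# ---------------------------------------------------------------------------
# shapes


def _linear(b: _Builder, spec: FixtureSpec, *, annotation: Optional[int] = None,
            tasks: int = 2, terminate: bool = False) -> None:
    names = _names(spec, tasks)
    start = b.add("start", "start_event", pattern_annotation=annotation)
    task_ids = [b.add(n, "task", n) for n in names]
    end = b.add("end", "terminate_end_event" if terminate else "end_event")
    b.chain(start, *task_ids, end)


def _gateway_block(b: _Builder, spec: FixtureSpec, *, split_kind: str, tag: str,
                   conditions, annotation: Optional[int] = None,
                   quorum: Optional[int] = None) -> None:
    k = spec.resolved_branches()
    names = _names(spec, k)
    start = b.add("start", "start_event")
    split = b.add(f"{tag}_split", split_kind, _SPLIT_NAMES[split_kind],
                  pattern_annotation=annotation, quorum=quorum)
    join_kind = "exclusive_gateway" if split_kind == "event_based_gateway" else split_kind
    join = b.add(f"{tag}_join" if split_kind != "event_based_gateway" else "xor_join",
                 join_kind)
    end = b.add("end", "end_event")
    b.flow(start, split)
    for i, name in enumerate(names):
        task = b.add(name, "task", name)
        if split_kind == "event_based_gateway":
            event = b.add(f"msg_{i + 1}", "intermediate_message_event")
            b.flow(split, event)
            b.flow(event, task)
        else:
            b.flow(split, task, condition=conditions(i, k))
        b.flow(task, join)
    b.flow(join, end)


_SPLIT_NAMES = {
    "exclusive_gateway": "exclusive_choice",
    "parallel_gateway": "parallel_split",
    "inclusive_gateway": "multi_choice",
    "event_based_gateway": "deferred_choice",
}


def _xor_conditions(i: int, k: int) -> str:
    if k == 2:
        return XOR_CONDITION if i == 0 else XOR_CONDITION_NEG
    return f'option="{i + 1}"'


def _or_conditions(i: int, k: int) -> str:
    return f"indication_{i + 1}"


def _adhoc(b: _Builder, spec: FixtureSpec, *, annotation: Optional[int] = None,
           partial_order: bool = False) -> None:
    k = spec.resolved_branches()
    names = _names(spec, k)
    start = b.add("start", "start_event")
    children = tuple(FlowNode(b.nid(n), "task", n) for n in names)
    adhoc = b.nid("adhoc")
    b.nodes.append(FlowNode(
        adhoc, "adhoc_subprocess", "interleaved_routing",
        children=children, ordering="sequential",
        completion_condition=ADHOC_COMPLETION,
        pattern_annotation=annotation,
    ))
    if partial_order:
        b.flow(children[0].node_id, children[1].node_id)
    end = b.add("end", "end_event")
    b.flow(start, adhoc)
    b.flow(adhoc, end)


def _loop(b: _Builder, spec: FixtureSpec) -> None:
    names = _names(spec, 1)
    start = b.add("start", "start_event")
    entry = b.add("loop_entry", "exclusive_gateway", "loop_entry")
    task = b.add(names[0], "task", names[0])
    exit_gw = b.add("loop_exit", "exclusive_gateway", "loop_exit")
    end = b.add("end", "end_event")
    b.flow(start, entry)
    b.flow(entry, task)
    b.flow(task, exit_gw)
    b.flow(exit_gw, entry, condition='not (followup_complete="yes")')
    b.flow(exit_gw, end, condition='followup_complete="yes"')


def _trigger(b: _Builder, spec: FixtureSpec, *, persistent: bool) -> None:
    names = _names(spec, 2)
    start = b.add("start", "start_event")
    task_a = b.add(names[0], "task", names[0])
    event = b.add("msg_catch", "intermediate_message_event",
                  persistent=persistent)
    task_b = b.add(names[1], "task", names[1])
    end = b.add("end", "end_event")
    b.chain(start, task_a, event, task_b, end)
    trig_start = b.add("trig_start", "start_message_event")
    trig = b.add("trigger_action", "task", "trigger_action")
    trig_end = b.add("trig_end", "end_event")
    b.chain(trig_start, trig, trig_end)
    b.triggers.append(Trigger(event=event, source=trig))


_SHAPES = {
    1: lambda b, s: _linear(b, s),
    2: lambda b, s: _gateway_block(b, s, split_kind="parallel_gateway", tag="and",
                                   conditions=lambda i, k: None),
    3: lambda b, s: _gateway_block(b, s, split_kind="parallel_gateway", tag="and",
                                   conditions=lambda i, k: None),
    4: lambda b, s: _gateway_block(b, s, split_kind="exclusive_gateway", tag="xor",
                                   conditions=_xor_conditions),
    5: lambda b, s: _gateway_block(b, s, split_kind="exclusive_gateway", tag="xor",
                                   conditions=_xor_conditions),
    6: lambda b, s: _gateway_block(b, s, split_kind="inclusive_gateway", tag="or",
                                   conditions=_or_conditions),
    7: lambda b, s: _gateway_block(b, s, split_kind="inclusive_gateway", tag="or",
                                   conditions=_or_conditions),
    9: lambda b, s: _gateway_block(b, s, split_kind="parallel_gateway", tag="and",
                                   conditions=lambda i, k: None, annotation=9,
                                   quorum=1),
    11: lambda b, s: _linear(b, s, annotation=11),
    16: lambda b, s: _gateway_block(b, s, split_kind="event_based_gateway", tag="evb",
                                    conditions=lambda i, k: None),
    17: lambda b, s: _adhoc(b, s, annotation=17, partial_order=True),
    18: lambda b, s: _linear(b, s, annotation=18),
    19: lambda b, s: _linear(b, s, annotation=19),
    20: lambda b, s: _linear(b, s, annotation=20),
    21: _loop,
    23: lambda b, s: _trigger(b, s, persistent=False),
    24: lambda b, s: _trigger(b, s, persistent=True),
    25: lambda b, s: _linear(b, s, annotation=25, tasks=3),
    30: lambda b, s: _gateway_block(
        b, s, split_kind="parallel_gateway", tag="and",
        conditions=lambda i, k: None, annotation=30,
        quorum=max(2, s.resolved_branches() - 1)),
    39: lambda b, s: _gateway_block(b, s, split_kind="parallel_gateway", tag="and",
                                    conditions=lambda i, k: None, annotation=39),
    40: lambda b, s: _adhoc(b, s),
    43: lambda b, s: _linear(b, s, terminate=True),
}


def relevant_fixture_ids() -> list[int]:
    """Ids of every pattern for which a canonical fixture exists (the 22
    guideline-relevant patterns)."""
    return [p.id for p in catalog.relevant_patterns()]


# ---------------------------------------------------------------------------
# composition


def _rename(process: BpmnProcess, prefix: str) -> BpmnProcess:
    def r(node_id: str) -> str:
        return f"{prefix}{node_id}"

    def rn(node: FlowNode) -> FlowNode:
        return replace(node, node_id=r(node.node_id),
                       children=tuple(rn(c) for c in node.children))

    return BpmnProcess(
        process.process_id,
        [rn(n) for n in process.nodes],
        [replace(f, flow_id=r(f.flow_id), source=r(f.source), target=r(f.target))
         for f in process.flows],
        [Trigger(event=r(t.event), source=r(t.source)) for t in process.triggers],
    )


def generate_composition(spec_list: Sequence[FixtureSpec], seed: int = 0) -> BpmnProcess:
    """Nest fixtures by substituting each one for a task of the previous.

    The first spec is the outer model; every later fixture replaces one of
    the current task nodes (chosen deterministically from ``seed``), its
    start/end plumbing stripped.  Composed fixtures must be single-branch
    (no trigger fixtures inside a composition).  Structuredness is preserved
    by construction.
    """
    if not spec_list:
        raise FixtureSpecError("composition needs at least one fixture spec")
    rng = random.Random(seed)
    current = generate_fixture(spec_list[0])
    for i, spec in enumerate(spec_list[1:], 1):
        inner = _rename(generate_fixture(spec), f"c{i}_")
        starts = [n for n in inner.nodes if n.kind == "start_event"]
        ends = [n for n in inner.nodes if n.kind == "end_event"]
        if len(starts) != 1 or len(ends) != 1 or inner.triggers:
            raise FixtureSpecError(
                f"pattern #{spec.pattern_id} cannot be nested inside a composition "
                f"(needs a single plain start/end branch)"
            )
        entry = inner.outgoing(starts[0].node_id)[0].target
        exit_ = inner.incoming(ends[0].node_id)[0].source
        drop = {starts[0].node_id, ends[0].node_id}
        core_nodes = [n for n in inner.nodes if n.node_id not in drop]
        core_flows = [f for f in inner.flows
                      if f.source not in drop and f.target not in drop]

        tasks = sorted(n.node_id for n in current.nodes if n.kind == "task")
        if not tasks:
            raise FixtureSpecError("outer fixture has no task to substitute")
        target = rng.choice(tasks)
        new_nodes: list[FlowNode] = []
        for n in current.nodes:
            if n.node_id == target:
                new_nodes.extend(core_nodes)
            else:
                new_nodes.append(n)
        new_flows = []
        for f in current.flows:
            if f.source == target:
                f = replace(f, source=exit_)
            if f.target == target:
                f = replace(f, target=entry)
            new_flows.append(f)
        current = BpmnProcess(current.process_id, new_nodes,
                              new_flows + core_flows, current.triggers)
    current.process_id = "composition_" + "_".join(
        f"p{s.pattern_id}" for s in spec_list
    )
    return current
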