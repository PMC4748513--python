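"""PROforma emitter: task networks from recognized BPMN pattern regions.

PROforma models care as a network of tasks (plans, actions, decisions,
enquiries) linked by scheduling constraints; tasks without constraints run
in parallel by default.  The per-pattern mappings:

* sequence -> actions chained by ``completed(...)`` scheduling constraints;
* parallel split/join -> components sharing a predecessor constraint, the
  post-join component constrained on all branch completions;
* exclusive choice / simple merge -> a single-selection decision with one
  candidate per diverging arc (conditioned arcs contribute an argument and
  a recommendation; an unconditioned default arc is recommended when no
  argument applies); branch actions carry preconditions tying them to
  their candidate;
* multi-choice -> a multiple-selection decision (flagged for post-editing:
  synchronizing over non-taken branches needs manual refinement);
* deferred choice -> a single-selection decision without arguments;
* structured loop -> a sub-plan with a repeat condition;
* persistent trigger -> the intermediate message event is **not**
  materialized as a component; the target action inherits its scheduling
  constraint from the nearest preceding non-event task and receives a
  state trigger (``wait_condition``) on completion of the triggering task;
* transient trigger -> an event trigger on the target action;
* cancel activity/case/region -> abort condition on the action / root /
  a grouping sub-plan;
* explicit termination -> termination condition on the root plan.

Interleaved routing, interleaved parallel routing and critical section
cannot be expressed (enumerating task permutations would contradict the
patterns' rationale) and raise.

The concrete syntax written by :func:`serialize_proforma` is this
package's stable keyword-block dialect; users targeting Tallis will need a
syntax adaptation pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx

from . import catalog, conditions
from .bpmn import BpmnProcess, EVENT_KINDS
from .errors import InvariantError, NotImplementableError
from .recognize import Region, collapse_wrapper, decompose, detect_patterns


@dataclass(frozen=True)
class Candidate:
    name: str
    arguments: tuple[tuple[str, str], ...] = ()   # (support direction, condition)
    recommendation: Optional[str] = None


@dataclass(frozen=True)
class ProformaTask:
    name: str
    kind: str                                     # plan | action | decision | enquiry
    components: tuple[str, ...] = ()              # plans only
    scheduling_constraints: tuple[str, ...] = ()  # completed(<task>) predicates
    precondition: Optional[str] = None
    candidate_of: Optional[tuple[str, str]] = None  # (decision, candidate) link
    wait_condition: Optional[str] = None          # state trigger
    event_trigger: Optional[str] = None
    raises_event: Optional[str] = None
    termination_condition: Optional[str] = None
    abort_condition: Optional[str] = None
    repeat_condition: Optional[str] = None        # loop plans
    candidates: tuple[Candidate, ...] = ()
    choice_mode: Optional[str] = None             # decisions: single | multiple

    def __post_init__(self) -> None:
        if self.kind not in ("plan", "action", "decision", "enquiry"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if (self.kind == "decision") != bool(self.candidates):
            raise ValueError("candidates are required for decisions and forbidden "
                             "elsewhere")


@dataclass
class ProformaModel:
    tasks: list[ProformaTask]
    root: str
    needs_postediting: list[tuple[str, str]] = field(default_factory=list)

    def task(self, name: str) -> ProformaTask:
        for t in self.tasks:
            if t.name == name:
                return t
        raise KeyError(name)

    def constraint_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(t.name for t in self.tasks)
        for t in self.tasks:
            for c in t.scheduling_constraints:
                ast = conditions.try_parse(c)
                refs = conditions.completed_references(ast) if ast else set()
                for ref in refs:
                    g.add_edge(ref, t.name)
        return g

    def problems(self) -> list[str]:
        out: list[str] = []
        names = [t.name for t in self.tasks]
        if not self.tasks:
            out.append("model has no tasks")
        if len(set(names)) != len(names):
            out.append("task names are not unique")
        if self.tasks and self.root not in names:
            out.append(f"root plan {self.root!r} is not defined")
        known = set(names)
        g = self.constraint_graph()
        for t in self.tasks:
            for ref in g.predecessors(t.name):
                if ref not in known:
                    out.append(f"task {t.name!r} has a dangling scheduling "
                               f"constraint on {ref!r}")
            for comp in t.components:
                if comp not in known:
                    out.append(f"plan {t.name!r} lists undefined component {comp!r}")
        if not nx.is_directed_acyclic_graph(g):
            out.append("scheduling constraints are cyclic")
        return out


# ---------------------------------------------------------------------------
# transformation


class _ProformaBuilder:
    def __init__(self, process: BpmnProcess) -> None:
        self.p = process
        self.tasks: list[ProformaTask] = []
        self.postedit: list[tuple[str, str]] = []
        self._names: set[str] = set()

    def fresh(self, base: str) -> str:
        name, i = base, 1
        while name in self._names:
            i += 1
            name = f"{base}_{i}"
        self._names.add(name)
        return name

    def add(self, task: ProformaTask) -> str:
        self.tasks.append(task)
        return task.name

    def amend(self, name: str, **changes) -> None:
        for i, t in enumerate(self.tasks):
            if t.name == name:
                self.tasks[i] = replace(t, **changes)
                return
        raise KeyError(name)

    def node_label(self, node_id: str) -> str:
        node = self.p.node(node_id)
        return node.name or node.node_id

    @staticmethod
    def constraints(deps: list[str]) -> tuple[str, ...]:
        return tuple(f"completed({d})" for d in sorted(set(deps)))

    # -- region walk ------------------------------------------------------

    def build(self, region: Region, deps: list[str]) -> list[str]:
        """Emit components for ``region``; returns the exit component names
        the successors must await."""
        inner = collapse_wrapper(region, self.p)
        if inner is not None:
            return self.build(inner, deps)
        if region.kind == "leaf":
            node = region.leaf_node(self.p)
            if node.kind in EVENT_KINDS:
                return deps
            name = self.fresh(self.node_label(region.entry))
            self.add(ProformaTask(name, "action",
                                  scheduling_constraints=self.constraints(deps)))
            return [name]
        if region.kind == "block":
            return self.build_block(region, deps)
        if region.kind == "loop":
            return self.build_loop(region, deps)
        if region.kind == "process":
            return self.build_trigger_process(region)
        return self.build_sequence(region, deps)

    def build_sequence(self, region: Region, deps: list[str]) -> list[str]:
        annotation = self.p.node(region.entry).pattern_annotation
        first = len(self.tasks)
        wait: Optional[str] = None
        for child in region.children:
            if child.kind == "leaf":
                node = child.leaf_node(self.p)
                if node.kind == "intermediate_message_event":
                    # the event is not materialized; the nearest preceding
                    # non-event task stays the scheduling predecessor and the
                    # trigger becomes a state trigger on the next action
                    trig = [t for t in self.p.triggers if t.event == child.entry]
                    if trig:
                        wait = f"completed({self.node_label(trig[0].source)})"
                    continue
            before = len(self.tasks)
            deps = self.build(child, deps)
            if wait is not None and len(self.tasks) > before:
                self.amend(self.tasks[before].name, wait_condition=wait)
                wait = None
        if annotation is not None:
            self._annotate_sequence(annotation,
                                    [t.name for t in self.tasks[first:]])
        return deps

    def _annotate_sequence(self, annotation: int, names: list[str]) -> None:
        if annotation == 18 and names:
            # milestone: direct via a precondition on the target action
            self.amend(names[-1], precondition="milestone_holds")
        elif annotation == 19 and names:
            self.amend(names[0], abort_condition="cancellation_required")
        elif annotation == 25 and len(names) >= 2:
            group = self.fresh("cancellable_region")
            self.add(ProformaTask(group, "plan", components=tuple(names[:-1]),
                                  abort_condition="region_cancellation_required"))
        # 11 (implicit termination) and 20/43 (root conditions, handled by the
        # caller) need no per-component change here

    def build_block(self, region: Region, deps: list[str]) -> list[str]:
        node = region.leaf_node(self.p)
        split_kind = region.meta["split_kind"]
        flows = region.meta["flows"]
        annotation = node.pattern_annotation
        if split_kind == "parallel_gateway" or annotation in (9, 30):
            exits: list[str] = []
            for branch in region.children:
                exits.extend(self.build(branch, deps))
            return exits
        # choice blocks become decision tasks
        decision = self.fresh(self.node_label(region.entry))
        mode = "multiple" if split_kind == "inclusive_gateway" else "single"
        cands: list[Candidate] = []
        exits = []
        for branch, flow in zip(region.children, flows):
            before = len(self.tasks)
            branch_exits = self.build(branch, [decision])
            added = self.tasks[before:]
            cand_base = added[0].name if added else f"branch_{len(cands) + 1}"
            cand_name = f"cand_{cand_base}"
            if flow.condition is not None and not flow.is_default:
                if not conditions.is_formalized(flow.condition):
                    self.postedit.append((
                        decision,
                        f"argument condition {flow.condition!r} is a free string; "
                        f"formalize it manually",
                    ))
                cands.append(Candidate(
                    cand_name,
                    arguments=(("for", flow.condition),),
                    recommendation=f"netsupport({decision}, {cand_name}) >= 1",
                ))
            else:
                # default / event-resolved arc: recommended when no argument
                # for a sibling applies
                cands.append(Candidate(cand_name,
                                       recommendation="no other candidate applies"))
            for t in added:
                if not t.candidate_of and t.kind == "action" \
                        and f"completed({decision})" in t.scheduling_constraints:
                    self.amend(t.name, candidate_of=(decision, cand_name),
                               precondition=f'result_of({decision}) = "{cand_name}"')
                    break
            exits.extend(branch_exits if added else [decision])
        self.add(ProformaTask(decision, "decision",
                              scheduling_constraints=self.constraints(deps),
                              candidates=tuple(cands), choice_mode=mode))
        if mode == "multiple":
            self.postedit.append((
                decision,
                "multi-choice decision: synchronization of the merge over "
                "non-taken branches needs manual refinement",
            ))
        return exits

    def build_loop(self, region: Region, deps: list[str]) -> list[str]:
        before = len(self.tasks)
        body_exits = self.build(region.children[0], [])
        body_names = [t.name for t in self.tasks[before:]]
        name = self.fresh("followup_loop")
        self.add(ProformaTask(
            name, "plan", components=tuple(body_names),
            scheduling_constraints=self.constraints(deps),
            repeat_condition=region.meta.get("repeat_condition")
            or region.meta.get("exit_condition") or "repeat",
        ))
        return [name]

    def build_trigger_process(self, region: Region) -> list[str]:
        trig = self.p.triggers[0]
        persistent = self.p.node(trig.event).persistent in (None, True)
        trigger_label = self.node_label(trig.source)
        exits: list[str] = []
        target_name: Optional[str] = None
        out = self.p.outgoing(trig.event)
        target_node = out[0].target if out else None
        for branch in region.children:
            before = len(self.tasks)
            exits.extend(self.build(branch, []))
            for t in self.tasks[before:]:
                if target_node and t.name == self.node_label(target_node):
                    target_name = t.name
        has_message_start = any(n.kind == "start_message_event" for n in self.p.nodes)
        if has_message_start:
            self.amend(trigger_label, event_trigger="external_request")
        if persistent:
            pass  # wait_condition already attached during the branch walk
        else:
            # transient trigger: an event trigger on the target instead of a
            # state trigger
            self.amend(trigger_label, raises_event="trigger_signal")
            if target_name:
                self.amend(target_name, event_trigger="trigger_signal",
                           wait_condition=None)
        return exits


def transform_to_proforma(process: BpmnProcess) -> ProformaModel:
    """Compile a structured BPMN process into a PROforma task network.

    Raises :class:`NotImplementableError` for interleaved routing,
    interleaved parallel routing and critical section, and propagates
    structuredness errors.
    """
    instances = detect_patterns(process)
    for inst in instances:
        if inst.pattern_id is None:
            continue
        entry = catalog.implementability(inst.pattern_id, "proforma")
        if entry.label == "not_implementable":
            raise NotImplementableError(inst.pattern_id, "proforma")
    builder = _ProformaBuilder(process)
    root_region = decompose(process)
    builder.build(root_region, [])
    component_names = tuple(
        t.name for t in builder.tasks
        if not any(t.name in other.components for other in builder.tasks)
    )
    root_kw = {}
    if any(n.kind == "terminate_end_event" for n in process.nodes):
        root_kw["termination_condition"] = "terminate_state_reached"
    annotations = {n.pattern_annotation for n in process.nodes}
    if 20 in annotations:
        root_kw["abort_condition"] = "case_cancellation_required"
    root_name = process.process_id
    builder.add(ProformaTask(root_name, "plan", components=component_names,
                             **root_kw))
    model = ProformaModel(builder.tasks, root_name, builder.postedit)
    problems = model.problems()
    if problems:
        raise InvariantError("; ".join(problems))
    return model


# ---------------------------------------------------------------------------
# serialization


def serialize_proforma(model: ProformaModel) -> str:
    """Deterministic keyword-block text in the package's PROforma dialect."""
    problems = model.problems()
    if problems:
        raise InvariantError("; ".join(problems))
    lines: list[str] = []
    for t in model.tasks:
        lines.append(f"{t.kind} :: '{t.name}'")
        if t.components:
            lines.append("  components : " + ", ".join(f"'{c}'" for c in t.components))
        for c in t.scheduling_constraints:
            lines.append(f"  schedule_constraint : {c}")
        if t.choice_mode:
            lines.append(f"  choice_mode : {t.choice_mode}")
        if t.precondition:
            lines.append(f"  precondition : {t.precondition}")
        if t.wait_condition:
            lines.append(f"  wait_condition : {t.wait_condition}")
        if t.event_trigger:
            lines.append(f"  trigger : {t.event_trigger}")
        if t.raises_event:
            lines.append(f"  raises : {t.raises_event}")
        if t.repeat_condition:
            lines.append(f"  repeat_until : {t.repeat_condition}")
        if t.abort_condition:
            lines.append(f"  abort_condition : {t.abort_condition}")
        if t.termination_condition:
            lines.append(f"  termination_condition : {t.termination_condition}")
        for cand in t.candidates:
            lines.append(f"  candidate :: '{cand.name}'")
            for direction, cond in cand.arguments:
                lines.append(f"    argument : {direction}, {cond}")
            if cand.recommendation:
                lines.append(f"    recommendation : {cand.recommendation}")
        lines.append(f"end {t.kind}.")
        lines.append("")
    return "\n".join(lines)
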