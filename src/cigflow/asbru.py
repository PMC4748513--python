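"""Asbru emitter: plan hierarchies from recognized BPMN pattern regions.

Asbru organizes care as a hierarchy of plans whose bodies prescribe how
subplans run (``sequentially``, ``parallel``, ``any-order``), optionally
constrained by a ``wait-for`` expression, and guarded by filter/abort/
complete conditions.  The per-pattern mappings:

* sequence -> sequential plan;
* parallel split/join -> parallel plan;
* exclusive choice / simple merge -> any-order plan with ``wait-for one``
  and mutually exclusive filter preconditions on the alternatives;
* multi-choice / synchronizing merge -> parallel plan whose children carry
  (non-exclusive) filter preconditions;
* deferred choice -> any-order plan with ``wait-for one`` and no filters
  (the environment resolves the choice);
* interleaved routing / critical section / interleaved parallel routing ->
  any-order plan with ``wait-for all`` (one subplan at a time);
* discriminator / partial join -> parallel plan with a quorum wait-for;
* structured loop -> cyclical plan carrying the exit condition;
* cancel activity/case/region -> a (grouping) plan with an abort condition;
* explicit termination -> complete condition on the root plan;
* milestone and persistent trigger -> workaround encodings via auxiliary
  boolean variables (set by a ``single_action`` plan, tested in the
  target's filter precondition), logged in ``needs_postediting``.

The transient trigger pattern cannot be expressed and raises.

The emitted XML uses the element vocabulary plan / plan-body / subplans /
wait-for / plan-activation / plan-schema / filter-precondition /
abort-condition / complete-condition without binding to a specific Asbru
schema version.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

from lxml import etree

from . import catalog, conditions
from .bpmn import BpmnProcess, EVENT_KINDS
from .errors import InvariantError, NotImplementableError
from .recognize import Region, classify, collapse_wrapper, decompose

BODY_KINDS = frozenset({
    "sequentially", "parallel", "any_order", "if_then_else", "cyclical",
    "user_performed", "single_action",
})

#: wait-for: None, "one", "all", or ("quorum", n)
WaitFor = Union[None, str, tuple]


@dataclass(frozen=True)
class AsbruPlan:
    name: str
    body_kind: str
    wait_for: WaitFor = None
    subplan_activations: tuple[str, ...] = ()
    filter_precondition: Optional[str] = None
    abort_condition: Optional[str] = None
    complete_condition: Optional[str] = None
    retry_spec: Optional[str] = None          # loop exit condition / schedule text
    sets_variable: Optional[str] = None       # single_action workaround plans

    def __post_init__(self) -> None:
        if self.body_kind not in BODY_KINDS:
            raise ValueError(f"unknown plan body kind {self.body_kind!r}")
        if self.wait_for is not None and self.body_kind not in ("any_order", "parallel"):
            raise ValueError("wait_for is only meaningful for any-order/parallel plans")


@dataclass
class AsbruModel:
    plans: list[AsbruPlan]
    root: str
    needs_postediting: list[tuple[str, str]] = field(default_factory=list)

    def plan(self, name: str) -> AsbruPlan:
        for p in self.plans:
            if p.name == name:
                return p
        raise KeyError(name)

    def aux_variables(self) -> dict[str, str]:
        """Auxiliary workaround variables -> name of the plan setting them."""
        return {p.sets_variable: p.name for p in self.plans if p.sets_variable}

    def problems(self) -> list[str]:
        out: list[str] = []
        names = [p.name for p in self.plans]
        if len(set(names)) != len(names):
            out.append("plan names are not unique")
        if not self.plans:
            out.append("model has no plans")
        elif self.root not in names:
            out.append(f"root plan {self.root!r} is not defined")
        for p in self.plans:
            for sub in p.subplan_activations:
                if sub not in names:
                    out.append(f"plan {p.name!r} activates undefined plan {sub!r}")
        return out


# ---------------------------------------------------------------------------
# transformation


class _AsbruBuilder:
    def __init__(self, process: BpmnProcess) -> None:
        self.p = process
        self.plans: list[AsbruPlan] = []
        self.postedit: list[tuple[str, str]] = []
        self._names: set[str] = set()

    def fresh(self, base: str) -> str:
        name, i = base, 1
        while name in self._names:
            i += 1
            name = f"{base}_{i}"
        self._names.add(name)
        return name

    def add(self, plan: AsbruPlan) -> str:
        self.plans.append(plan)
        return plan.name

    def amend(self, name: str, **changes) -> None:
        for i, p in enumerate(self.plans):
            if p.name == name:
                self.plans[i] = replace(p, **changes)
                return
        raise KeyError(name)

    def node_label(self, node_id: str) -> str:
        node = self.p.node(node_id)
        return node.name or node.node_id

    # -- region walk ------------------------------------------------------

    def build(self, region: Region) -> list[str]:
        """Plans realizing ``region``, in activation order."""
        inner = collapse_wrapper(region, self.p)
        if inner is not None:
            return self.build(inner)
        if region.kind == "leaf":
            node = region.leaf_node(self.p)
            if node.kind in EVENT_KINDS:
                return []
            name = self.fresh(self.node_label(region.entry))
            return [self.add(AsbruPlan(name, "user_performed"))]
        if region.kind == "adhoc":
            return [self.build_adhoc(region)]
        if region.kind == "block":
            return [self.build_block(region)]
        if region.kind == "loop":
            return [self.build_loop(region)]
        if region.kind == "process":
            return [self.build_trigger_process(region)]
        return self.build_sequence(region)

    def wrap(self, names: list[str], base: str, **plan_kw) -> str:
        """A single plan activating ``names`` (pass-through when singular)."""
        if len(names) == 1 and not plan_kw:
            return names[0]
        name = self.fresh(base)
        return self.add(AsbruPlan(name, "sequentially",
                                  subplan_activations=tuple(names), **plan_kw))

    def build_sequence(self, region: Region) -> list[str]:
        annotation = self.p.node(region.entry).pattern_annotation
        names: list[str] = []
        for child in region.children:
            names.extend(self.build(child))
        if annotation is None:
            return names
        return [self._annotated_sequence(annotation, region, names)]

    def _annotated_sequence(self, annotation: int, region: Region,
                            names: list[str]) -> str:
        if annotation == 11:
            # implicit termination: the plan completes when nothing is left
            # to do, which is the default plan semantics
            return self.wrap(names, "implicit_termination")
        if annotation == 18:
            # milestone workaround: an auxiliary variable set after the
            # source, tested (with the milestone validity) by the target
            var = "reached_milestone"
            setter = self.add(AsbruPlan(self.fresh("set_" + var), "single_action",
                                        sets_variable=var))
            target = names[-1]
            self.amend(target, filter_precondition=f"{var} and milestone_holds")
            wrapped = self.wrap(names[:-1] + [setter, target], "milestone")
            self.postedit.append((
                wrapped,
                "milestone workaround: auxiliary variable "
                f"'{var}' and the validity condition 'milestone_holds' must be "
                "formalized manually",
            ))
            return wrapped
        if annotation == 19:
            group = self.add(AsbruPlan(
                self.fresh("cancellable_" + names[0]), "sequentially",
                subplan_activations=(names[0],),
                abort_condition="cancellation_required",
            ))
            return self.wrap([group] + names[1:], "cancel_activity")
        if annotation == 20:
            return self.wrap(names, "cancel_case",
                             abort_condition="case_cancellation_required")
        if annotation == 25:
            group = self.add(AsbruPlan(
                self.fresh("cancellable_region"), "sequentially",
                subplan_activations=tuple(names[:-1]),
                abort_condition="region_cancellation_required",
            ))
            wrapped = self.wrap([group] + names[-1:], "cancel_region")
            self.postedit.append((
                wrapped,
                "cancel-region workaround: a grouping plan with an abort "
                "condition was introduced; the abort condition must be "
                "formalized manually",
            ))
            return wrapped
        return self.wrap(names, f"pattern_{annotation}")

    def build_adhoc(self, region: Region) -> str:
        node = region.leaf_node(self.p)
        subplans = []
        by_child: dict[str, str] = {}
        for child in node.children:
            name = self.fresh(child.name or child.node_id)
            by_child[child.node_id] = name
            subplans.append(self.add(AsbruPlan(name, "user_performed")))
        # partial-order flows inside the sub-process become state-predicate
        # filter preconditions (interleaved parallel routing)
        for f in self.p.internal_flows(node):
            self.amend(by_child[f.target],
                       filter_precondition=f"completed({by_child[f.source]})")
        name = self.fresh(self.node_label(region.entry))
        return self.add(AsbruPlan(name, "any_order", wait_for="all",
                                  subplan_activations=tuple(subplans)))

    def build_block(self, region: Region) -> str:
        node = region.leaf_node(self.p)
        split_kind = region.meta["split_kind"]
        flows = region.meta["flows"]
        annotation = node.pattern_annotation
        base = self.node_label(region.entry)
        branch_names = [self.wrap(self.build(br) or
                                  [self.add(AsbruPlan(self.fresh("empty_branch"),
                                                      "user_performed"))],
                                  f"{base}_branch_{i + 1}")
                        for i, br in enumerate(region.children)]
        if annotation == 39:
            return self.add(AsbruPlan(self.fresh(base), "any_order", wait_for="all",
                                      subplan_activations=tuple(branch_names)))
        if annotation in (9, 30):
            quorum = 1 if annotation == 9 else (node.quorum or len(branch_names) - 1)
            return self.add(AsbruPlan(self.fresh(base), "parallel",
                                      wait_for=("quorum", quorum),
                                      subplan_activations=tuple(branch_names)))
        if split_kind == "parallel_gateway":
            return self.add(AsbruPlan(self.fresh(base), "parallel", wait_for="all",
                                      subplan_activations=tuple(branch_names)))
        if split_kind == "event_based_gateway":
            return self.add(AsbruPlan(self.fresh(base), "any_order", wait_for="one",
                                      subplan_activations=tuple(branch_names)))
        if split_kind == "inclusive_gateway":
            self._attach_filters(branch_names, flows, exclusive=False)
            return self.add(AsbruPlan(self.fresh(base), "parallel", wait_for="all",
                                      subplan_activations=tuple(branch_names)))
        # exclusive choice - simple merge
        self._attach_filters(branch_names, flows, exclusive=True)
        return self.add(AsbruPlan(self.fresh(base), "any_order", wait_for="one",
                                  subplan_activations=tuple(branch_names)))

    def _attach_filters(self, branch_names: list[str], flows, exclusive: bool) -> None:
        sibling_conditions = [f.condition for f in flows
                              if f.condition and not f.is_default]
        formalized = all(conditions.is_formalized(c) for c in sibling_conditions)
        texts: list[Optional[str]] = []
        for name, f in zip(branch_names, flows):
            if f.condition is not None and not f.is_default:
                if not conditions.is_formalized(f.condition):
                    self.postedit.append((
                        name,
                        f"condition {f.condition!r} is a free string and was "
                        f"copied verbatim; formalize it manually",
                    ))
                texts.append(f.condition)
            elif formalized and sibling_conditions:
                # default/unconditioned arc: none of the siblings holds
                texts.append(conditions.negated_disjunction(sibling_conditions))
            else:
                texts.append("otherwise")
                self.postedit.append((
                    name,
                    "default branch condition could not be derived from "
                    "unformalized sibling conditions; 'otherwise' marker emitted",
                ))
            self.amend(name, filter_precondition=texts[-1])
        if exclusive and formalized:
            pairs = [(a, b) for i, a in enumerate(texts) for b in texts[i + 1:]]
            if not all(conditions.mutually_exclusive(a, b) for a, b in pairs
                       if a != "otherwise" and b != "otherwise"):
                self.postedit.append((
                    branch_names[0],
                    "exclusive-choice conditions could not be proven mutually "
                    "exclusive; review them manually",
                ))

    def build_loop(self, region: Region) -> str:
        body = self.wrap(self.build(region.children[0]), "loop_body")
        exit_condition = region.meta.get("exit_condition") or "loop_exit"
        name = self.fresh(self.node_label(region.entry).replace("loop_entry", "loop")
                          or "loop")
        return self.add(AsbruPlan(name, "cyclical", subplan_activations=(body,),
                                  retry_spec=exit_condition))

    def build_trigger_process(self, region: Region) -> str:
        trig = self.p.triggers[0]
        var = "trigger_received"
        branch_plans: list[str] = []
        target_task = None
        out = self.p.outgoing(trig.event)
        if out:
            target_task = out[0].target
        for branch in region.children:
            names: list[str] = []
            for child in branch.children:
                built = self.build(child)
                names.extend(built)
                if child.kind == "leaf" and child.entry == trig.source:
                    setter = self.add(AsbruPlan(self.fresh("set_" + var),
                                                "single_action", sets_variable=var))
                    names.append(setter)
                if built and child.kind == "leaf" and child.entry == target_task:
                    self.amend(built[0], filter_precondition=var)
            branch_plans.append(self.wrap(names, "branch_" + branch.entry))
        root = self.add(AsbruPlan(self.fresh("persistent_trigger"), "parallel",
                                  wait_for="all",
                                  subplan_activations=tuple(branch_plans)))
        self.postedit.append((
            root,
            f"persistent-trigger workaround: auxiliary variable '{var}' mimics "
            f"the trigger and must be maintained manually",
        ))
        return root


def transform_to_asbru(process: BpmnProcess) -> AsbruModel:
    """Compile a structured BPMN process into an Asbru plan hierarchy.

    Raises :class:`NotImplementableError` when the process contains a
    transient trigger, and propagates structuredness errors.
    """
    from .recognize import detect_patterns

    instances = detect_patterns(process)
    for inst in instances:
        if inst.pattern_id is None:
            continue
        entry = catalog.implementability(inst.pattern_id, "asbru")
        if entry.label == "not_implementable":
            raise NotImplementableError(inst.pattern_id, "asbru")
    builder = _AsbruBuilder(process)
    root = decompose(process)
    names = builder.build(root)
    root_name = builder.wrap(names, process.process_id)
    # explicit termination: complete condition on the top-level plan
    terminates = [n for n in process.nodes if n.kind == "terminate_end_event"]
    if terminates:
        builder.amend(root_name, complete_condition="terminate_state_reached")
    model = AsbruModel(builder.plans, root_name, builder.postedit)
    problems = model.problems()
    if problems:
        raise InvariantError("; ".join(problems))
    return model


# ---------------------------------------------------------------------------
# serialization


_WAIT_TEXT = {"one": "one", "all": "all"}
_BODY_TAGS = {"sequentially": "sequentially", "parallel": "parallel",
              "any_order": "any-order"}


def serialize_asbru(model: AsbruModel) -> str:
    """Emit the model as one XML document (deterministic element order)."""
    problems = model.problems()
    if problems:
        raise InvariantError("; ".join(problems))
    root = etree.Element("plan-group", attrib={"root": model.root})
    for p in model.plans:
        plan_elem = etree.SubElement(root, "plan", attrib={"name": p.name})
        cond = etree.SubElement(plan_elem, "conditions")
        if p.filter_precondition:
            etree.SubElement(cond, "filter-precondition").text = p.filter_precondition
        if p.abort_condition:
            etree.SubElement(cond, "abort-condition").text = p.abort_condition
        if p.complete_condition:
            etree.SubElement(cond, "complete-condition").text = p.complete_condition
        if not len(cond):
            plan_elem.remove(cond)
        body = etree.SubElement(plan_elem, "plan-body")
        if p.body_kind in _BODY_TAGS:
            subplans = etree.SubElement(body, "subplans",
                                        attrib={"type": _BODY_TAGS[p.body_kind]})
            if p.wait_for is not None:
                wf = etree.SubElement(subplans, "wait-for")
                if isinstance(p.wait_for, tuple):
                    wf.set("count", str(p.wait_for[1]))
                else:
                    wf.text = _WAIT_TEXT[p.wait_for]
            for sub in p.subplan_activations:
                act = etree.SubElement(subplans, "plan-activation")
                etree.SubElement(act, "plan-schema", attrib={"name": sub})
        elif p.body_kind == "cyclical":
            cyc = etree.SubElement(body, "cyclical-plan-body")
            if p.retry_spec:
                etree.SubElement(cyc, "retry-spec").text = p.retry_spec
            for sub in p.subplan_activations:
                act = etree.SubElement(cyc, "plan-activation")
                etree.SubElement(act, "plan-schema", attrib={"name": sub})
        elif p.body_kind == "single_action":
            etree.SubElement(body, "single-action",
                             attrib={"variable": p.sets_variable or p.name,
                                     "value": "true"})
        else:
            etree.SubElement(body, "user-performed")
    return etree.tostring(root, pretty_print=True, encoding="unicode")
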