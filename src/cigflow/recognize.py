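"""Region decomposition and workflow-pattern recognition.

A structured process decomposes into a tree of single-entry/single-exit
(SESE) regions: sequences, split/join blocks, post-test loops, and ad hoc
sub-processes.  :func:`decompose` builds that tree; :func:`detect_patterns`
labels regions with workflow-pattern identities so the emitters can
dispatch per pattern.

Labelling is structural where BPMN determines the pattern (gateway blocks,
loops, ad hoc sub-processes, triggers, terminate events) and annotation
driven where it does not (milestone, cancellation, critical section,
interleaved parallel routing, discriminator/partial join, implicit
termination) — see the dialect notes in :mod:`cigflow.bpmn`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from . import catalog
from .bpmn import (
    BpmnProcess, EVENT_KINDS, GATEWAY_KINDS, START_KINDS, FlowNode,
    StructurednessReport,
)
from .errors import StructurednessError

_JOIN_KIND_FOR_SPLIT = {
    "exclusive_gateway": "exclusive_gateway",
    "parallel_gateway": "parallel_gateway",
    "inclusive_gateway": "inclusive_gateway",
    # no converging event-based gateway exists in BPMN; the dialect closes a
    # deferred choice with an exclusive merge
    "event_based_gateway": "exclusive_gateway",
}

#: ids recognized only through the cig:pattern annotation convention
ANNOTATION_PATTERNS = frozenset({9, 11, 17, 18, 19, 20, 25, 30, 39})


@dataclass
class Region:
    """A single-entry/single-exit fragment of the process graph."""

    kind: str                      # leaf | sequence | block | loop | adhoc | process
    entry: str
    exit: str
    members: frozenset[str]
    children: list["Region"] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def leaf_node(self, process: BpmnProcess) -> FlowNode:
        return process.node(self.entry)


@dataclass
class PatternInstance:
    """A region labelled with a workflow-pattern identity.

    ``pattern_ids`` lists every id the region jointly realizes (a split/join
    block realizes both members of its pair, e.g. ``(4, 5)``);
    ``pattern_id`` is the primary (split) id, or ``None`` for an
    ``unknown_fragment``.
    """

    pattern_id: Optional[int]
    pattern_ids: tuple[int, ...]
    region: Region
    roles: dict[str, str]


# ---------------------------------------------------------------------------
# region parsing


class _RegionParser:
    def __init__(self, process: BpmnProcess) -> None:
        self.p = process
        self.g = process.graph()
        self.violations: list[tuple[str, str]] = []
        self.back_edges: set[tuple[str, str]] = set()
        self._find_back_edges()

    def _find_back_edges(self) -> None:
        """Back edges of structured loops: iteratively peel each strongly
        connected component at its unique entry (loop-nesting forest)."""
        g2 = self.g.copy()
        for _ in range(len(self.g) + 1):
            found = False
            for scc in list(nx.strongly_connected_components(g2)):
                if len(scc) < 2:
                    continue
                entries = sorted(
                    v for v in scc
                    if any(u not in scc for u in g2.predecessors(v))
                )
                if len(entries) != 1:
                    self.violate(min(scc),
                                 "cycle with multiple entry points (arbitrary, "
                                 "non-structured loop)")
                    g2.remove_edges_from([(u, v) for v in scc
                                          for u in g2.predecessors(v) if u in scc])
                    found = True
                    continue
                entry = entries[0]
                for u in list(g2.predecessors(entry)):
                    if u in scc:
                        self.back_edges.add((u, entry))
                        g2.remove_edge(u, entry)
                found = True
            if not found:
                break

    def back_preds(self, n: str) -> list[str]:
        return sorted(u for u in self.g.predecessors(n) if (u, n) in self.back_edges)

    def fwd_in_degree(self, n: str) -> int:
        return sum(1 for u in self.g.predecessors(n) if (u, n) not in self.back_edges)

    def violate(self, node: str, reason: str) -> None:
        self.violations.append((node, reason))

    # -- top level --------------------------------------------------------

    def parse(self) -> Optional[Region]:
        branches: list[Region] = []
        for comp in sorted(nx.weakly_connected_components(self.g), key=min):
            starts = sorted(
                v for v in comp
                if self.p.node(v).kind in START_KINDS and self.g.in_degree(v) == 0
            )
            if len(starts) != 1:
                self.violate(min(comp), f"branch has {len(starts)} start events, expected 1")
                continue
            region = self.parse_sequence(starts[0], stop=None)
            if region is not None:
                branches.append(region)
        if not branches:
            return None
        if len(branches) == 1:
            return branches[0]
        # put the branch starting from a plain start event first (the main one)
        branches.sort(
            key=lambda r: (self.p.node(r.entry).kind != "start_event", r.entry)
        )
        members = frozenset().union(*(b.members for b in branches))
        return Region("process", branches[0].entry, branches[0].exit, members,
                      children=branches)

    # -- sequences --------------------------------------------------------

    def parse_sequence(self, entry: str, stop: Optional[str]) -> Optional[Region]:
        children: list[Region] = []
        members: set[str] = set()
        cur: Optional[str] = entry
        for _ in range(len(self.g) * 4 + 8):
            if cur is None or cur == stop:
                break
            node = self.p.node(cur)
            if cur != entry and not self.back_preds(cur) and self.fwd_in_degree(cur) > 1:
                self.violate(cur, "multiple incoming flows outside any split-join "
                                  "region (improper nesting)")
                return None
            out = self.p.outgoing(cur)
            if self.back_preds(cur):
                parsed = self.parse_loop(cur)
            elif node.kind in GATEWAY_KINDS and len(out) > 1:
                parsed = self.parse_block(cur)
            elif len(out) > 1:
                self.violate(cur, f"{node.kind} node has multiple outgoing flows")
                return None
            else:
                leaf_members = {cur} | {c.node_id for c in node.children}
                leaf = Region("adhoc" if node.kind == "adhoc_subprocess" else "leaf",
                              cur, cur, frozenset(leaf_members),
                              children=[Region("leaf", c.node_id, c.node_id,
                                               frozenset({c.node_id}))
                                        for c in node.children])
                parsed = (leaf, out[0].target if out else None)
            if parsed is None:
                return None
            region, cur = parsed
            children.append(region)
            members |= region.members
        else:
            self.violate(entry, "region walk did not terminate (cyclic structure)")
            return None
        if not children:
            return Region("sequence", stop or entry, stop or entry, frozenset())
        return Region("sequence", children[0].entry, children[-1].exit,
                      frozenset(members), children)

    # -- split/join blocks ------------------------------------------------

    def parse_block(self, split: str):
        node = self.p.node(split)
        branch_flows = self.p.outgoing(split)
        expected = _JOIN_KIND_FOR_SPLIT[node.kind]
        joins = []
        for f in branch_flows:
            j = self.find_merge(f.target)
            if j is None:
                return None
            joins.append(j)
        if len(set(joins)) != 1:
            self.violate(split, "branches do not converge on a single matching join")
            return None
        join = joins[0]
        join_node = self.p.node(join)
        if join_node.kind != expected:
            self.violate(split, f"{node.kind} split closed by {join_node.kind} join "
                                f"(kind mismatch)")
            return None
        if self.fwd_in_degree(join) != len(branch_flows):
            self.violate(join, "join receives flows from outside the region "
                               "(improper nesting)")
        branches: list[Region] = []
        members: set[str] = {split, join}
        for f in branch_flows:
            if f.target == join:
                branches.append(Region("sequence", join, join, frozenset()))
            else:
                br = self.parse_sequence(f.target, stop=join)
                if br is None:
                    return None
                branches.append(br)
                members |= br.members
        for m in sorted(members - {split}):
            for u in self.g.predecessors(m):
                if u not in members and m != join:
                    self.violate(m, "flow enters the region from outside "
                                    "(improper nesting)")
        out = self.p.outgoing(join)
        if len(out) > 1:
            self.violate(join, "join gateway also diverges; split and join must be "
                               "separate elements")
            return None
        region = Region("block", split, join, frozenset(members), branches,
                        meta={"split_kind": node.kind, "flows": branch_flows})
        return region, (out[0].target if out else None)

    def find_merge(self, start: str) -> Optional[str]:
        cur = start
        for _ in range(len(self.g) * 4 + 8):
            node = self.p.node(cur)
            back = self.back_preds(cur)
            if not back and self.fwd_in_degree(cur) > 1:
                if node.kind in GATEWAY_KINDS:
                    return cur
                self.violate(cur, "multiple incoming flows into a non-gateway node")
                return None
            if back:
                loop_split = back[0]
                nxt = [f.target for f in self.p.outgoing(loop_split) if f.target != cur]
                if len(nxt) != 1:
                    self.violate(loop_split, "loop exit gateway must have exactly one "
                                             "forward flow")
                    return None
                cur = nxt[0]
                continue
            out = self.p.outgoing(cur)
            if node.kind in GATEWAY_KINDS and len(out) > 1:
                inner = self.find_merge(out[0].target)
                if inner is None:
                    return None
                inner_out = self.p.outgoing(inner)
                if not inner_out:
                    self.violate(inner, "branch reaches a dead end before a matching join")
                    return None
                cur = inner_out[0].target
                continue
            if not out:
                self.violate(cur, "branch reaches the end of the process before a "
                                  "matching join")
                return None
            cur = out[0].target
        self.violate(start, "merge search did not terminate")
        return None

    # -- loops ------------------------------------------------------------

    def parse_loop(self, entry: str):
        node = self.p.node(entry)
        if node.kind != "exclusive_gateway":
            self.violate(entry, f"loop entry must be an exclusive gateway, got {node.kind}")
            return None
        back = self.back_preds(entry)
        if len(back) != 1:
            self.violate(entry, "loop entry must have exactly one back edge")
            return None
        loop_split = back[0]
        split_node = self.p.node(loop_split)
        if split_node.kind != "exclusive_gateway":
            self.violate(loop_split, f"loop must be closed by an exclusive gateway, "
                                     f"got {split_node.kind}")
            return None
        out = self.p.outgoing(entry)
        if len(out) != 1:
            self.violate(entry, "loop entry gateway must have a single outgoing flow")
            return None
        body = self.parse_sequence(out[0].target, stop=loop_split)
        if body is None:
            return None
        exit_flows = [f for f in self.p.outgoing(loop_split) if f.target != entry]
        back_flows = [f for f in self.p.outgoing(loop_split) if f.target == entry]
        if len(exit_flows) != 1:
            self.violate(loop_split, "loop exit gateway must have exactly one exit flow")
            return None
        members = frozenset({entry, loop_split} | body.members)
        region = Region("loop", entry, loop_split, members, [body],
                        meta={"exit_condition": exit_flows[0].condition,
                              "repeat_condition": back_flows[0].condition})
        return region, exit_flows[0].target


def _parse_process(process: BpmnProcess):
    parser = _RegionParser(process)
    root = parser.parse()
    return root, parser.violations


# ---------------------------------------------------------------------------
# operations


def decompose(process: BpmnProcess) -> Region:
    """Region tree of a structured process; raises on structuredness violations."""
    root, violations = _parse_process(process)
    if violations or root is None:
        report = StructurednessReport(False, tuple(violations))
        raise StructurednessError(report)
    return root


def _is_event_leaf(region: Region, process: BpmnProcess) -> bool:
    return region.kind == "leaf" and process.node(region.entry).kind in EVENT_KINDS


def _task_leaves(region: Region, process: BpmnProcess) -> list[str]:
    return [c.entry for c in region.children
            if c.kind == "leaf" and process.node(c.entry).kind == "task"]


def _branch_roles(region: Region, process: BpmnProcess) -> dict[str, str]:
    roles = {"diverging_gateway": region.entry, "converging_gateway": region.exit}
    for i, (branch, flow) in enumerate(zip(region.children, region.meta["flows"]), 1):
        roles[f"branch_{i}"] = branch.entry
        if flow.is_default:
            roles["default_branch"] = branch.entry
    return roles


def classify(region: Region, process: BpmnProcess):
    """Pattern identity of one region, or ``None`` for unlabelled plumbing.

    Returns ``(pattern_ids, roles)``.  Regions never get a label they cannot
    be proven to carry; ambiguous fragments stay unlabelled.
    """
    entry_node = process.node(region.entry)
    annotation = entry_node.pattern_annotation
    if annotation is not None and region.kind != "leaf":
        return (annotation,), _annotation_roles(annotation, region, process)
    if region.kind == "block":
        split_kind = region.meta["split_kind"]
        ids = {
            "exclusive_gateway": (4, 5),
            "parallel_gateway": (2, 3),
            "inclusive_gateway": (6, 7),
            "event_based_gateway": (16,),
        }[split_kind]
        return ids, _branch_roles(region, process)
    if region.kind == "loop":
        body = region.children[0]
        return (21,), {"loop_entry": region.entry, "loop_exit": region.exit,
                       "body": body.entry}
    if region.kind == "adhoc":
        node = process.node(region.entry)
        if node.ordering == "sequential":
            roles = {"subprocess": region.entry}
            for i, child in enumerate(node.children, 1):
                roles[f"branch_{i}"] = child.node_id
            return (40,), roles
        return None
    if region.kind == "process":
        if process.triggers:
            trig = process.triggers[0]
            event = process.node(trig.event)
            out = process.outgoing(trig.event)
            roles = {"trigger_source": trig.source, "trigger_event": trig.event}
            if out:
                roles["target"] = out[0].target
            pid = 24 if event.persistent in (None, True) else 23
            return (pid,), roles
        return None
    if region.kind == "sequence":
        last = region.children[-1] if region.children else None
        if last is not None and last.kind == "leaf" \
                and process.node(last.entry).kind == "terminate_end_event":
            roles = {"terminate_event": last.entry}
            for i, t in enumerate(_task_leaves(region, process), 1):
                roles[f"task_{i}"] = t
            return (43,), roles
        tasks = _task_leaves(region, process)
        non_event = [c for c in region.children if not _is_event_leaf(c, process)]
        if len(non_event) >= 2:
            return (1,), {f"task_{i}": t for i, t in enumerate(tasks, 1)}
        return None
    return None


def _annotation_roles(annotation: int, region: Region, process: BpmnProcess) -> dict:
    if region.kind == "block":
        roles = _branch_roles(region, process)
        if annotation == 30:
            roles["quorum"] = str(process.node(region.entry).quorum
                                  or max(2, len(region.children) - 1))
        elif annotation == 9:
            roles["quorum"] = "1"
        return roles
    if region.kind == "adhoc":
        node = process.node(region.entry)
        roles = {"subprocess": region.entry}
        for i, child in enumerate(node.children, 1):
            roles[f"branch_{i}"] = child.node_id
        return roles
    tasks = _task_leaves(region, process)
    roles = {f"task_{i}": t for i, t in enumerate(tasks, 1)}
    if annotation == 18 and len(tasks) >= 2:
        roles.update(milestone_source=tasks[0], target=tasks[1])
    elif annotation == 19 and tasks:
        roles["cancelled_activity"] = tasks[0]
    elif annotation == 25 and len(tasks) >= 2:
        roles["continuation"] = tasks[-1]
        for i, t in enumerate(tasks[:-1], 1):
            roles[f"region_task_{i}"] = t
    return roles


def collapse_wrapper(region: Region, process: BpmnProcess) -> Optional[Region]:
    """The single structural child of a trivial wrapper sequence, else None.

    The top-level sequence of a single-pattern model is just start/end
    plumbing around one block/loop/ad hoc region; pattern identity belongs
    to the inner region but is reported at the wrapper's span.
    """
    if region.kind != "sequence":
        return None
    if process.node(region.entry).pattern_annotation is not None:
        return None
    non_event = [c for c in region.children if not _is_event_leaf(c, process)]
    if len(non_event) == 1 and non_event[0].kind not in ("leaf",):
        return non_event[0]
    return None


def detect_patterns(process: BpmnProcess) -> list[PatternInstance]:
    """All labelled pattern instances of a structured process.

    Deterministic: instances are ordered by region entry node id.  Regions
    that are neither labellable nor trivial plumbing are reported as
    ``unknown_fragment`` instances with ``pattern_id None``.
    """
    root = decompose(process)
    instances: list[PatternInstance] = []

    def walk(region: Region) -> None:
        if region.kind == "leaf":
            return
        inner = collapse_wrapper(region, process)
        if inner is not None:
            label = classify(inner, process)
            if label is not None:
                ids, roles = label
                instances.append(PatternInstance(ids[0], ids, region, roles))
            for child in inner.children:
                walk(child)
            return
        label = classify(region, process)
        if label is not None:
            ids, roles = label
            instances.append(PatternInstance(ids[0], ids, region, roles))
        elif region.kind not in ("sequence", "process"):
            instances.append(PatternInstance(None, (), region, {}))
        for child in region.children:
            walk(child)

    walk(root)
    instances.sort(key=lambda i: i.region.entry)
    return instances


def top_instance(process: BpmnProcess) -> Optional[PatternInstance]:
    """The instance labelling the whole-process region, if any."""
    root = decompose(process)
    for inst in detect_patterns(process):
        if inst.region.members == root.members and inst.pattern_id is not None:
            return inst
    return None


def relevant_ids(process: BpmnProcess) -> set[int]:
    """All pattern ids detected anywhere in the process (primary ids)."""
    return {i.pattern_id for i in detect_patterns(process) if i.pattern_id is not None}
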