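"""Trace semantics: the acceptance oracle for emitted guideline models.

Both target languages compile onto one executable intermediate, a *task
system*: a flat set of task lifecycle automata plus structural constraints
(start-after dependencies, exclusive/multiple selections, one-at-a-time
mutex groups, quorum gates, cancellation scopes).  :func:`enumerate_traces`
exhaustively interleaves the system and returns the finite set of visible
execution traces; :func:`reference_traces` generates the expected trace set
of each workflow pattern in closed form, independently of the compilers;
:func:`check_equivalence` compares the two.

Conditions are abstracted to free booleans and both valuations are explored
(their content is opaque at this level), with one exception: state
predicates of the form ``completed(task)`` — and auxiliary workaround
variables that mimic them — are interpreted structurally as start-after
dependencies.  Loops are unrolled to ``loop_bound``; cancellation
atomically stops the running tasks of a scope (emitting ``cancelled``) and
withdraws its pending ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from . import conditions
from .asbru import AsbruModel
from .errors import SemanticsError
from .fixtures import FixtureSpec, _names
from .proforma import ProformaModel

Event = tuple[str, str]  # (task name, "started" | "completed" | "cancelled")
FINISHED = ("done", "cancelled", "discarded")


@dataclass(frozen=True, order=True)
class ExecutionTrace:
    events: tuple[Event, ...]

    def __iter__(self):
        return iter(self.events)


@dataclass(frozen=True)
class TraceSet:
    traces: frozenset[ExecutionTrace]
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.traces)

    def sorted(self) -> list[ExecutionTrace]:
        return sorted(self.traces)


# ---------------------------------------------------------------------------
# the task-system intermediate


@dataclass(frozen=True)
class SysTask:
    name: str       # internal, unique
    display: str    # name appearing in trace events
    silent: bool = False


@dataclass
class TaskSystem:
    tasks: dict[str, SysTask] = field(default_factory=dict)
    #: task -> internal names that must be finished before it may start
    after: dict[str, set[str]] = field(default_factory=dict)
    #: (selector id, [(option label, selected tasks)]); tasks in the
    #: selector's domain but not in the chosen option are withdrawn
    selectors: list[tuple[str, list[tuple[str, frozenset[str]]]]] = field(
        default_factory=list)
    #: groups of task blocks of which at most one may be in progress at a time
    mutex_groups: list[list[frozenset[str]]] = field(default_factory=list)
    #: (watched blocks, n, gated tasks): gated tasks may start once n of the
    #: watched blocks have fully finished
    quorum_gates: list[tuple[tuple[frozenset[str], ...], int, frozenset[str]]] = field(
        default_factory=list)
    #: (scope id, tasks): a cancellation may fire once while a scope task runs
    cancel_scopes: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def add_task(self, name: str, display: str, silent: bool = False) -> str:
        if name in self.tasks:
            raise SemanticsError(f"duplicate task {name!r} in task system")
        self.tasks[name] = SysTask(name, display, silent)
        self.after[name] = set()
        return name

    def add_after(self, tasks: Iterable[str], deps: Iterable[str]) -> None:
        deps = set(deps)
        for t in tasks:
            self.after[t] |= deps


def run_system(system: TaskSystem, max_steps: int = 64) -> TraceSet:
    """Exhaustive interleaving search over the task system's state space."""
    if max_steps < 1:
        raise SemanticsError("max_steps must be >= 1")
    names = sorted(system.tasks)
    traces: set[ExecutionTrace] = set()
    truncated = False

    option_lists = [opts for _, opts in system.selectors] or []
    combos = itertools.product(*option_lists) if option_lists else [()]

    for combo in combos:
        discarded: set[str] = set()
        for (sid, opts), (_, chosen) in zip(system.selectors, combo):
            domain = frozenset().union(*(o[1] for o in opts))
            discarded |= domain - chosen
        status = {n: ("discarded" if n in discarded else "pending") for n in names}
        used_scopes: set[str] = set()
        trace: list[Event] = []

        def finished(t: str) -> bool:
            return status[t] in FINISHED

        def block_in_progress(block: frozenset[str]) -> bool:
            begun = any(status[t] in ("running", "done", "cancelled") for t in block)
            return begun and not all(finished(t) for t in block)

        def can_start(t: str) -> bool:
            if not all(finished(d) for d in system.after[t]):
                return False
            for watch, n, gated in system.quorum_gates:
                if t in gated:
                    done_blocks = sum(1 for ws in watch if all(finished(x) for x in ws))
                    if done_blocks < n:
                        return False
            for group in system.mutex_groups:
                mine = [b for b in group if t in b]
                if mine:
                    others = [b for b in group if t not in b]
                    if any(block_in_progress(b) for b in others):
                        return False
            return True

        def dfs() -> None:
            nonlocal truncated
            if all(finished(n) for n in names):
                traces.add(ExecutionTrace(tuple(trace)))
                return
            if len(trace) >= max_steps:
                truncated = True
                return
            moves: list[tuple] = []
            for t in names:
                if status[t] == "running":
                    moves.append(("complete", t))
                elif status[t] == "pending" and can_start(t):
                    moves.append(("start", t))
            for sid, scope in system.cancel_scopes:
                if sid in used_scopes:
                    continue
                if any(status[t] == "running" for t in scope):
                    moves.append(("cancel", sid, scope))
            for move in moves:
                if move[0] == "start":
                    t = move[1]
                    status[t] = "running"
                    emitted = not system.tasks[t].silent
                    if emitted:
                        trace.append((system.tasks[t].display, "started"))
                    dfs()
                    if emitted:
                        trace.pop()
                    status[t] = "pending"
                elif move[0] == "complete":
                    t = move[1]
                    status[t] = "done"
                    emitted = not system.tasks[t].silent
                    if emitted:
                        trace.append((system.tasks[t].display, "completed"))
                    dfs()
                    if emitted:
                        trace.pop()
                    status[t] = "running"
                else:
                    _, sid, scope = move
                    saved = {t: status[t] for t in scope}
                    emitted: list[Event] = []
                    for t in sorted(scope, key=lambda x: system.tasks[x].display):
                        if status[t] == "running":
                            status[t] = "cancelled"
                            if not system.tasks[t].silent:
                                emitted.append((system.tasks[t].display, "cancelled"))
                        elif status[t] == "pending":
                            status[t] = "discarded"
                    used_scopes.add(sid)
                    trace.extend(emitted)
                    dfs()
                    del trace[len(trace) - len(emitted):]
                    used_scopes.discard(sid)
                    status.update(saved)

        dfs()

    if not traces and not truncated:
        raise SemanticsError("model has no reachable completion")
    return TraceSet(frozenset(traces), truncated)


# ---------------------------------------------------------------------------
# Asbru compilation


class _AsbruCompiler:
    def __init__(self, model: AsbruModel, loop_bound: int) -> None:
        self.m = model
        self.bound = loop_bound
        self.sys = TaskSystem()
        self.aux = model.aux_variables()       # variable -> setter plan name
        self.units: dict[tuple[str, str], frozenset[str]] = {}
        self.filters: list[tuple[frozenset[str], str, str, bool]] = []
        self._sid = 0

    def sid(self, base: str) -> str:
        self._sid += 1
        return f"{base}#{self._sid}"

    def compile(self) -> TaskSystem:
        self.plan_unit(self.m.root, "")
        self._resolve_filters()
        return self.sys

    def plan_unit(self, name: str, suffix: str,
                  consumed_filter: bool = False) -> frozenset[str]:
        plan = self.m.plan(name)
        internal = f"{name}{suffix}"
        if plan.body_kind in ("user_performed", "single_action"):
            self.sys.add_task(internal, plan.name, silent=plan.body_kind == "single_action")
            unit = frozenset({internal})
        elif plan.body_kind == "cyclical":
            iterations: list[frozenset[str]] = []
            for i in range(1, self.bound + 1):
                it = frozenset().union(*(
                    self.plan_unit(c, f"{suffix}@{i}")
                    for c in plan.subplan_activations
                )) if plan.subplan_activations else frozenset()
                if iterations:
                    self.sys.add_after(it, iterations[-1])
                iterations.append(it)
            options = []
            for i in range(1, self.bound + 1):
                chosen = frozenset().union(*iterations[:i])
                options.append((f"{i} iterations", chosen))
            self.sys.selectors.append((self.sid(internal), options))
            unit = frozenset().union(*iterations)
        else:
            child_filters = [self.m.plan(c).filter_precondition
                             for c in plan.subplan_activations]
            multichoice = (
                plan.body_kind == "parallel"
                and plan.subplan_activations
                and all(self._is_free_condition(c) for c in child_filters)
            )
            wait_one = plan.body_kind == "any_order" and plan.wait_for == "one"
            child_units = [
                self.plan_unit(c, suffix, consumed_filter=multichoice or wait_one)
                for c in plan.subplan_activations
            ]
            if plan.body_kind == "sequentially":
                for prev, nxt in zip(child_units, child_units[1:]):
                    self.sys.add_after(nxt, prev)
            elif wait_one:
                options = [(c, u) for c, u in
                           zip(plan.subplan_activations, child_units)]
                self.sys.selectors.append((self.sid(internal), options))
            elif plan.body_kind == "any_order":  # wait-for all: one at a time
                self.sys.mutex_groups.append(list(child_units))
            elif multichoice:
                options = []
                k = len(child_units)
                for r in range(1, k + 1):
                    for subset in itertools.combinations(range(k), r):
                        chosen = frozenset().union(*(child_units[i] for i in subset))
                        label = "+".join(plan.subplan_activations[i] for i in subset)
                        options.append((label, chosen))
                self.sys.selectors.append((self.sid(internal), options))
            elif isinstance(plan.wait_for, tuple):  # quorum release
                n = plan.wait_for[1]
                self.sys.quorum_gates.append((tuple(child_units), n, frozenset()))
            unit = frozenset().union(*child_units) if child_units else frozenset()
        self.units[(name, suffix)] = unit
        if plan.filter_precondition:
            self.filters.append((unit, plan.filter_precondition, suffix, consumed_filter))
        if plan.abort_condition:
            self.sys.cancel_scopes.append((self.sid(f"abort:{internal}"), unit))
        return unit

    @staticmethod
    def _is_free_condition(text: Optional[str]) -> bool:
        if not text:
            return False
        ast = conditions.try_parse(text)
        return ast is not None and not conditions.completed_references(ast)

    def _lookup(self, plan_name: str, suffix: str) -> Optional[frozenset[str]]:
        if (plan_name, suffix) in self.units:
            return self.units[(plan_name, suffix)]
        for (name, _), unit in self.units.items():
            if name == plan_name:
                return unit
        return None

    def _resolve_filters(self) -> None:
        for unit, text, suffix, consumed in self.filters:
            ast = conditions.try_parse(text)
            if ast is None:
                free: set[str] = set() if consumed else {text}
                refs: set[str] = set()
            else:
                refs = conditions.completed_references(ast)
                free = conditions.free_atoms(ast)
            for ref in sorted(refs):
                dep = self._lookup(ref, suffix)
                if dep is not None:
                    self.sys.add_after(unit, dep)
            for atom in sorted(free):
                if atom in self.aux:
                    dep = self._lookup(self.aux[atom], suffix)
                    if dep is not None:
                        self.sys.add_after(unit, dep)
                elif not consumed:
                    self.sys.selectors.append((
                        self.sid(f"guard:{atom}"),
                        [("holds", unit), ("fails", frozenset())],
                    ))


# ---------------------------------------------------------------------------
# PROforma compilation


class _ProformaCompiler:
    def __init__(self, model: ProformaModel, loop_bound: int) -> None:
        self.m = model
        self.bound = loop_bound
        self.sys = TaskSystem()
        self.units: dict[str, frozenset[str]] = {}  # component -> task set
        self._sid = 0

    def sid(self, base: str) -> str:
        self._sid += 1
        return f"{base}#{self._sid}"

    def compile(self) -> TaskSystem:
        raisers = {t.raises_event: t.name for t in self.m.tasks if t.raises_event}
        # components of repeat plans are templates; only their unrolled
        # per-iteration copies execute
        templates: set[str] = set()
        for t in self.m.tasks:
            if t.kind == "plan" and t.repeat_condition:
                templates |= set(t.components)
        # first pass: task units (loops unrolled)
        for t in self.m.tasks:
            if t.name in templates:
                continue
            if t.kind == "action":
                self.units[t.name] = frozenset({self.sys.add_task(t.name, t.name)})
            elif t.kind == "decision":
                self.units[t.name] = frozenset(
                    {self.sys.add_task(t.name, t.name, silent=True)})
        for t in self.m.tasks:
            if t.kind != "plan":
                continue
            if t.repeat_condition:
                iterations: list[frozenset[str]] = []
                for i in range(1, self.bound + 1):
                    copies = set()
                    for comp in t.components:
                        base = self.m.task(comp)
                        copies.add(self.sys.add_task(f"{comp}@{i}", comp,
                                                     silent=base.kind != "action"))
                    it = frozenset(copies)
                    # constraints internal to the body, per iteration
                    for comp in t.components:
                        base = self.m.task(comp)
                        for c in base.scheduling_constraints:
                            for ref in self._refs(c):
                                if ref in t.components:
                                    self.sys.add_after([f"{comp}@{i}"], [f"{ref}@{i}"])
                    if iterations:
                        self.sys.add_after(it, iterations[-1])
                    iterations.append(it)
                options = [(f"{i} iterations", frozenset().union(*iterations[:i]))
                           for i in range(1, self.bound + 1)]
                self.sys.selectors.append((self.sid(t.name), options))
                self.units[t.name] = frozenset().union(*iterations)
                for comp in t.components:
                    self.units[comp] = frozenset(
                        f"{comp}@{i}" for i in range(1, self.bound + 1))
            else:
                self.units[t.name] = frozenset().union(
                    *(self.units[c] for c in t.components)) if t.components \
                    else frozenset()

        # second pass: constraints, selections, guards, scopes
        for t in self.m.tasks:
            if t.name in templates:
                continue  # per-iteration constraints were wired during unroll
            unit = self.units[t.name]
            if t.kind == "plan" and t.repeat_condition:
                deps: set[str] = set()
                for c in t.scheduling_constraints:
                    deps |= self._dep_tasks(c)
                self.sys.add_after(unit, deps)
            elif t.kind != "plan":
                for c in t.scheduling_constraints:
                    self.sys.add_after(unit, self._dep_tasks(c))
            if t.wait_condition:
                self.sys.add_after(unit, self._dep_tasks(t.wait_condition))
            if t.event_trigger and t.event_trigger in raisers:
                self.sys.add_after(unit, self.units[raisers[t.event_trigger]])
            if t.precondition and not t.candidate_of:
                ast = conditions.try_parse(t.precondition)
                refs = conditions.completed_references(ast) if ast else set()
                if not refs:  # free condition: explore both valuations
                    self.sys.selectors.append((
                        self.sid(f"guard:{t.name}"),
                        [("holds", unit), ("fails", frozenset())],
                    ))
            if t.abort_condition:
                scope = unit if t.name != self.m.root else frozenset(
                    n for n, st in self.sys.tasks.items())
                self.sys.cancel_scopes.append((self.sid(f"abort:{t.name}"), scope))
            if t.kind == "decision":
                groups: dict[str, set[str]] = {c.name: set() for c in t.candidates}
                for other in self.m.tasks:
                    if other.candidate_of and other.candidate_of[0] == t.name:
                        groups[other.candidate_of[1]] |= self.units[other.name]
                cand_units = {name: frozenset(g) for name, g in groups.items()}
                if t.choice_mode == "multiple":
                    names = sorted(cand_units)
                    options = []
                    for r in range(1, len(names) + 1):
                        for subset in itertools.combinations(names, r):
                            chosen = frozenset().union(*(cand_units[n] for n in subset))
                            options.append(("+".join(subset), chosen))
                else:
                    options = [(n, cand_units[n]) for n in sorted(cand_units)]
                if options:
                    self.sys.selectors.append((self.sid(t.name), options))
        return self.sys

    @staticmethod
    def _refs(text: str) -> set[str]:
        ast = conditions.try_parse(text)
        return conditions.completed_references(ast) if ast else set()

    def _dep_tasks(self, constraint: str) -> set[str]:
        deps: set[str] = set()
        for ref in self._refs(constraint):
            if ref in self.units:
                deps |= self.units[ref]
        return deps


# ---------------------------------------------------------------------------
# operations


def enumerate_traces(model: Union[AsbruModel, ProformaModel],
                     max_steps: int = 64, loop_bound: int = 2) -> TraceSet:
    """All admissible execution traces of an emitted model.

    Conditions are branched over both valuations; loops are unrolled to
    ``loop_bound``; a trace exceeding ``max_steps`` events sets
    ``truncated`` instead of being silently dropped.
    """
    if loop_bound < 1 or max_steps < 1:
        raise SemanticsError("bounds must be >= 1")
    if isinstance(model, AsbruModel):
        system = _AsbruCompiler(model, loop_bound).compile()
    elif isinstance(model, ProformaModel):
        system = _ProformaCompiler(model, loop_bound).compile()
    else:
        raise SemanticsError(f"cannot enumerate traces of {type(model).__name__}")
    return run_system(system, max_steps=max_steps)


# -- reference semantics ----------------------------------------------------


def _block(name: str) -> tuple[Event, ...]:
    return ((name, "started"), (name, "completed"))


def _shuffles(seqs: Sequence[tuple[Event, ...]]) -> set[tuple[Event, ...]]:
    """All interleavings of the given event sequences (orders preserved)."""
    seqs = [s for s in seqs if s]
    if not seqs:
        return {()}
    out: set[tuple[Event, ...]] = set()
    for i, s in enumerate(seqs):
        rest = seqs[:i] + [s[1:]] + seqs[i + 1:]
        for tail in _shuffles(rest):
            out.add((s[0],) + tail)
    return out


def _concat_orders(blocks: Sequence[tuple[Event, ...]],
                   order_pairs: Sequence[tuple[int, int]] = ()) -> set[tuple[Event, ...]]:
    """Concatenations of whole blocks in every order consistent with the
    partial order given as index pairs (a before b)."""
    out: set[tuple[Event, ...]] = set()
    for perm in itertools.permutations(range(len(blocks))):
        pos = {p: i for i, p in enumerate(perm)}
        if all(pos[a] < pos[b] for a, b in order_pairs):
            out.add(tuple(e for i in perm for e in blocks[i]))
    return out


def _cancellations(full: tuple[Event, ...],
                   scope: set[str]) -> set[tuple[Event, ...]]:
    """Truncations of ``full`` where the case/scope is cancelled while at
    least one scope task is running; the suffix outside the scope is dropped."""
    out: set[tuple[Event, ...]] = set()
    for k in range(1, len(full) + 1):
        prefix = full[:k]
        running = sorted({name for name, a in prefix if a == "started" and name in scope}
                         - {name for name, a in prefix if a == "completed"})
        if running:
            out.add(prefix + tuple((r, "cancelled") for r in running))
    return out


def reference_traces(pattern_id: int, spec: Optional[FixtureSpec] = None,
                     loop_bound: int = 2) -> TraceSet:
    """Closed-form expected trace set of a workflow pattern.

    Generated directly from the pattern's published behavioral description,
    independently of the BPMN fixtures and of both compilers; task names
    follow the canonical fixture naming so emitted models compare without
    renaming.
    """
    from . import catalog
    descriptor = catalog.get_pattern(pattern_id)
    if not descriptor.relevant:
        raise SemanticsError(
            f"pattern #{pattern_id} is not relevant; no reference semantics")
    spec = spec or FixtureSpec(pattern_id)
    k = spec.resolved_branches()
    names = _names(spec, max(k, 2) if pattern_id != 25 else 3)
    blocks = [_block(n) for n in names[:k]]
    t: set[tuple[Event, ...]] = set()

    if pattern_id in (1, 11):
        t = {tuple(e for n in names[:2] for e in _block(n))}
    elif pattern_id in (2, 3, 9, 30):
        # branches in free interleaving; the (partial-)join's early release
        # is unobservable without a downstream task
        t = _shuffles(blocks)
    elif pattern_id in (4, 5, 16):
        t = {b for b in blocks}
    elif pattern_id in (6, 7):
        for r in range(1, k + 1):
            for subset in itertools.combinations(range(k), r):
                t |= _shuffles([blocks[i] for i in subset])
    elif pattern_id in (39, 40):
        t = _concat_orders(blocks)
    elif pattern_id == 17:
        t = _concat_orders(blocks, order_pairs=[(0, 1)])
    elif pattern_id == 18:
        a, b = names[0], names[1]
        t = {_block(a) + _block(b), _block(a)}
    elif pattern_id == 19:
        a, b = names[0], names[1]
        t = {_block(a) + _block(b),
             ((a, "started"), (a, "cancelled")) + _block(b)}
    elif pattern_id == 20:
        full = _block(names[0]) + _block(names[1])
        t = {full} | _cancellations(full, {names[0], names[1]})
    elif pattern_id == 21:
        body = _block(names[0])
        t = {body * i for i in range(1, loop_bound + 1)}
    elif pattern_id in (23, 24):
        main = _block(names[0]) + _block(names[1])
        trig = _block("trigger_action")
        for cand in _shuffles([main, trig]):
            start_b = cand.index((names[1], "started"))
            done_t = cand.index(("trigger_action", "completed"))
            if done_t < start_b:
                t.add(cand)
    elif pattern_id == 25:
        a, b, c = names[0], names[1], names[2]
        full = _block(a) + _block(b)
        t = {full + _block(c)}
        t |= {cut + _block(c) for cut in _cancellations(full, {a, b})}
    elif pattern_id == 43:
        t = {tuple(e for n in names[:2] for e in _block(n))}
    else:  # pragma: no cover
        raise SemanticsError(f"no reference semantics for pattern #{pattern_id}")
    return TraceSet(frozenset(ExecutionTrace(x) for x in t))


# -- equivalence ------------------------------------------------------------


@dataclass(frozen=True)
class EquivalenceResult:
    equivalent: bool
    missing: tuple[ExecutionTrace, ...]  # expected but not observed
    extra: tuple[ExecutionTrace, ...]    # observed but not expected

    def __bool__(self) -> bool:
        return self.equivalent

    def report(self) -> str:
        if self.equivalent:
            return "trace sets are equivalent"
        lines = [f"trace sets differ ({len(self.missing)} missing, "
                 f"{len(self.extra)} extra)"]
        for tr in self.missing:
            lines.append("  missing: " + "; ".join(f"{n} {a}" for n, a in tr))
        for tr in self.extra:
            lines.append("  extra:   " + "; ".join(f"{n} {a}" for n, a in tr))
        return "\n".join(lines)


def check_equivalence(observed: TraceSet, expected: TraceSet,
                      renaming: Optional[dict[str, str]] = None) -> EquivalenceResult:
    """Set equality of trace sets, up to a task renaming of the observed side."""
    if observed.truncated != expected.truncated:
        raise SemanticsError(
            "cannot compare a truncated trace set against a complete one")
    if renaming:
        observed = TraceSet(frozenset(
            ExecutionTrace(tuple((renaming.get(n, n), a) for n, a in tr))
            for tr in observed.traces), observed.truncated)
    missing = tuple(sorted(expected.traces - observed.traces))
    extra = tuple(sorted(observed.traces - expected.traces))
    return EquivalenceResult(not missing and not extra, missing, extra)
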