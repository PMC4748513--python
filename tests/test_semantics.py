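"""Trace enumeration, reference semantics, and equivalence checking."""

import itertools

import pytest

from cigflow import (
    FixtureSpec, check_equivalence, enumerate_traces, generate_fixture,
    reference_traces, transform_to_asbru, transform_to_proforma,
)
from cigflow import catalog
from cigflow.errors import SemanticsError
from cigflow.fixtures import _names
from cigflow.semantics import ExecutionTrace, TraceSet


# ---------------------------------------------------------------------------
# independent oracle: permutations of lifecycle events filtered by the
# pattern's declarative constraints (never generated compositionally)


_LOOP_FREE = [1, 2, 3, 4, 5, 6, 7, 9, 11, 16, 17, 18, 19, 20, 23, 24, 25,
              30, 39, 40, 43]


def _pattern_scenarios(pattern_id: int, spec: FixtureSpec):
    """Declarative per-pattern constraints for the loop-free fixtures.

    Each scenario is ``(outcomes, precedence, atomic)``: the tasks that run
    with their finish event (``completed`` or ``cancelled``), pairs
    ``(a, b)`` meaning b may only start after a finished, and whether task
    executions must not overlap in time.
    """
    k = spec.resolved_branches()
    names = _names(spec, max(k, 2) if pattern_id != 25 else 3)
    branch = names[:k]
    done = "completed"

    def run(tasks, precedence=(), atomic=False, cancelled=()):
        outcomes = {t: ("cancelled" if t in cancelled else done) for t in tasks}
        return outcomes, list(precedence), atomic

    a, b = names[0], names[1]
    if pattern_id in (1, 11, 43):
        return [run([a, b], [(a, b)])]
    if pattern_id in (2, 3, 9, 30):
        return [run(branch)]
    if pattern_id in (4, 5, 16):
        return [run([n]) for n in branch]
    if pattern_id in (6, 7):
        return [run(list(c)) for r in range(1, k + 1)
                for c in itertools.combinations(branch, r)]
    if pattern_id in (39, 40):
        return [run(branch, atomic=True)]
    if pattern_id == 17:
        return [run(branch, [(a, b)], atomic=True)]
    if pattern_id == 18:  # milestone may have expired: the target is skipped
        return [run([a, b], [(a, b)]), run([a])]
    if pattern_id == 19:  # the activity completes or is withdrawn mid-run
        return [run([a, b], [(a, b)]),
                run([a, b], [(a, b)], cancelled=[a])]
    if pattern_id == 20:  # the whole case may be cancelled while a task runs
        return [run([a, b], [(a, b)]),
                run([a], cancelled=[a]),
                run([a, b], [(a, b)], cancelled=[b])]
    if pattern_id in (23, 24):
        tasks = [a, b, "trigger_action"]
        return [run(tasks, [(a, b), ("trigger_action", b)])]
    if pattern_id == 25:  # region {A, B} cancellable, C continues regardless
        c = names[2]
        return [run([a, b, c], [(a, b), (b, c)]),
                run([a, c], [(a, c)], cancelled=[a]),
                run([a, b, c], [(a, b), (b, c)], cancelled=[b])]
    raise ValueError(pattern_id)


def brute_force_traces(pattern_id: int, spec: FixtureSpec) -> set[tuple]:
    """Enumerate every permutation of the lifecycle event multiset and keep
    the ones satisfying the pattern's declarative constraints."""
    out: set[tuple] = set()
    for outcomes, precedence, atomic in _pattern_scenarios(pattern_id, spec):
        tasks = list(outcomes)
        events = [(t, a) for t in tasks for a in ("started", outcomes[t])]
        for perm in set(itertools.permutations(events)):
            index = {e: i for i, e in enumerate(perm)}
            if any(index[(t, "started")] > index[(t, outcomes[t])] for t in tasks):
                continue
            if any(index[(y, "started")] < index[(x, outcomes[x])]
                   for x, y in precedence if x in tasks and y in tasks):
                continue
            if atomic and any(
                index[(x, "started")] < index[(y, "started")]
                < index[(x, outcomes[x])]
                for x in tasks for y in tasks if x != y
            ):
                continue
            out.add(perm)
    return out


def _implementable(language):
    return [p for p in _LOOP_FREE
            if catalog.implementability(p, language).label != "not_implementable"]


class TestBruteForceCrossCheck:
    @pytest.mark.parametrize("pattern_id", _implementable("asbru"))
    def test_asbru_trace_counts(self, pattern_id):
        spec = FixtureSpec(pattern_id)
        model = transform_to_asbru(generate_fixture(spec))
        observed = enumerate_traces(model)
        assert len(observed) == len(brute_force_traces(pattern_id, spec))

    @pytest.mark.parametrize("pattern_id", _implementable("proforma"))
    def test_proforma_trace_counts(self, pattern_id):
        spec = FixtureSpec(pattern_id)
        model = transform_to_proforma(generate_fixture(spec))
        observed = enumerate_traces(model)
        assert len(observed) == len(brute_force_traces(pattern_id, spec))

    @pytest.mark.parametrize("pattern_id", _LOOP_FREE)
    def test_reference_matches_brute_force_exactly(self, pattern_id):
        spec = FixtureSpec(pattern_id)
        expected = {t.events for t in reference_traces(pattern_id, spec).traces}
        assert expected == brute_force_traces(pattern_id, spec)


class TestEnumerateTraces:
    def test_sequence_has_single_trace(self):
        model = transform_to_asbru(generate_fixture(FixtureSpec(1)))
        ts = enumerate_traces(model)
        assert len(ts) == 1
        (trace,) = ts.traces
        assert trace.events == (("action_A", "started"), ("action_A", "completed"),
                                ("action_B", "started"), ("action_B", "completed"))

    def test_interleaved_routing_enumerates_orderings(self):
        model = transform_to_asbru(generate_fixture(FixtureSpec(40, branch_count=3)))
        ts = enumerate_traces(model)
        assert len(ts) == 6  # 3! strictly sequential orderings

    def test_exclusive_choice_branches_over_valuations(self):
        model = transform_to_proforma(generate_fixture(FixtureSpec(4)))
        ts = enumerate_traces(model)
        assert len(ts) == 2
        for trace in ts.traces:
            names = {n for n, _ in trace.events}
            assert names in ({"action_A"}, {"action_B"})

    def test_loop_unrolls_to_bound(self):
        model = transform_to_asbru(generate_fixture(FixtureSpec(21)))
        for bound in (1, 2, 3):
            ts = enumerate_traces(model, loop_bound=bound)
            assert len(ts) == bound  # 1..bound iterations

    def test_truncation_is_flagged_not_silent(self):
        model = transform_to_asbru(generate_fixture(FixtureSpec(2, branch_count=3)))
        ts = enumerate_traces(model, max_steps=3)
        assert ts.truncated

    def test_bad_bounds_rejected(self):
        model = transform_to_asbru(generate_fixture(FixtureSpec(1)))
        with pytest.raises(SemanticsError):
            enumerate_traces(model, loop_bound=0)


class TestReferenceTraces:
    def test_sequence_reference(self):
        assert len(reference_traces(1)) == 1

    def test_parallel_reference_interleaves(self):
        ts = reference_traces(2)
        assert len(ts) == 6
        for trace in ts.traces:
            index = {e: i for i, e in enumerate(trace.events)}
            assert index[("action_A", "started")] < index[("action_A", "completed")]

    def test_loop_reference_repeats_body(self):
        ts = reference_traces(21, loop_bound=2)
        lengths = sorted(len(t.events) for t in ts.traces)
        assert lengths == [2, 4]

    def test_cancel_case_truncates_prefixes(self):
        ts = reference_traces(20)
        cancelled = [t for t in ts.traces
                     if any(a == "cancelled" for _, a in t.events)]
        assert len(cancelled) == 2  # cancelled during either task

    def test_non_relevant_pattern_rejected(self):
        with pytest.raises(SemanticsError, match="not relevant"):
            reference_traces(12)


class TestCheckEquivalence:
    def test_identical_sets(self):
        ts = reference_traces(4)
        assert check_equivalence(ts, ts)

    def test_wrong_emission_is_detected_with_diff(self):
        """Interleaved routing emitted as plain parallelism exhibits
        overlapping-execution traces the reference forbids."""
        wrong = enumerate_traces(
            transform_to_asbru(generate_fixture(FixtureSpec(2))))  # parallel
        expected = reference_traces(40, FixtureSpec(40, branch_count=2))
        result = check_equivalence(wrong, expected)
        assert not result
        assert result.extra and not result.missing
        assert "extra" in result.report()

    def test_renaming_is_applied(self):
        ts = reference_traces(1, FixtureSpec(1, task_names=["X", "Y"]))
        expected = reference_traces(1)
        renamed = check_equivalence(ts, expected,
                                    renaming={"X": "action_A", "Y": "action_B"})
        assert renamed

    def test_truncation_mismatch_rejected(self):
        ts = reference_traces(1)
        truncated = TraceSet(ts.traces, truncated=True)
        with pytest.raises(SemanticsError, match="truncated"):
            check_equivalence(truncated, ts)


class TestFullMatrixEquivalence:
    """Every implementable cell of the matrix is trace-equivalent to the
    pattern's reference semantics at loop bound 2."""

    @pytest.mark.parametrize("language, pattern_id", [
        (lang, p.id)
        for lang in ("asbru", "proforma")
        for p in catalog.relevant_patterns()
        if catalog.implementability(p.id, lang).label != "not_implementable"
    ])
    def test_cell(self, pattern_id, language):
        transform = transform_to_asbru if language == "asbru" \
            else transform_to_proforma
        spec = FixtureSpec(pattern_id)
        model = transform(generate_fixture(spec))
        observed = enumerate_traces(model, max_steps=64, loop_bound=2)
        expected = reference_traces(pattern_id, spec, loop_bound=2)
        result = check_equivalence(observed, expected)
        assert result, result.report()
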