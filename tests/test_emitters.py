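"""Asbru and PROforma emitters: per-pattern mapping conformance."""

import pytest

from cigflow import (
    FixtureSpec, generate_fixture, serialize_asbru, serialize_proforma,
    transform_to_asbru, transform_to_proforma,
)
from cigflow import catalog, conditions
from cigflow.asbru import AsbruModel, AsbruPlan
from cigflow.errors import InvariantError, NotImplementableError
from cigflow.proforma import ProformaModel, ProformaTask


def asbru_model(pattern_id, **spec_kw):
    return transform_to_asbru(generate_fixture(FixtureSpec(pattern_id, **spec_kw)))


def proforma_model(pattern_id, **spec_kw):
    return transform_to_proforma(generate_fixture(FixtureSpec(pattern_id, **spec_kw)))


class TestAsbruMappings:
    def test_exclusive_choice_is_any_order_wait_one(self):
        model = asbru_model(4)
        root = model.plan(model.root)
        assert root.name == "exclusive_choice"
        assert root.body_kind == "any_order" and root.wait_for == "one"
        assert len(root.subplan_activations) == 2
        subs = [model.plan(n) for n in root.subplan_activations]
        assert all(s.filter_precondition for s in subs)

    def test_exclusive_choice_conditions_are_mutually_exclusive(self):
        model = asbru_model(4, branch_count=3)
        root = model.plan(model.root)
        conds = [model.plan(n).filter_precondition
                 for n in root.subplan_activations]
        source = generate_fixture(FixtureSpec(4, branch_count=3))
        conditioned = [f.condition for f in source.outgoing("p4_xor_split")]
        assert len(conds) == len(conditioned)
        for i, a in enumerate(conds):
            for b in conds[i + 1:]:
                assert conditions.mutually_exclusive(a, b)

    def test_interleaved_routing_is_any_order_wait_all(self):
        model = asbru_model(40, branch_count=3)
        root = model.plan(model.root)
        assert root.body_kind == "any_order" and root.wait_for == "all"
        assert len(root.subplan_activations) == 3

    def test_parallel_split(self):
        model = asbru_model(2)
        assert model.plan(model.root).body_kind == "parallel"

    def test_loop_is_cyclical_with_exit_condition(self):
        model = asbru_model(21)
        root = model.plan(model.root)
        assert root.body_kind == "cyclical"
        assert root.retry_spec == 'followup_complete="yes"'

    def test_cancel_region_groups_with_abort_condition(self):
        model = asbru_model(25)
        groups = [p for p in model.plans if p.abort_condition]
        assert len(groups) == 1
        assert len(groups[0].subplan_activations) == 2  # all but the last task

    def test_explicit_termination_sets_complete_condition(self):
        model = asbru_model(43)
        assert model.plan(model.root).complete_condition

    def test_transient_trigger_not_implementable(self):
        with pytest.raises(NotImplementableError, match="#23.*asbru"):
            asbru_model(23)

    @pytest.mark.parametrize("pattern_id", [18, 24, 25])
    def test_workaround_patterns_are_flagged_for_postediting(self, pattern_id):
        assert asbru_model(pattern_id).needs_postediting

    @pytest.mark.parametrize("pattern_id", [1, 2, 4, 6, 9, 11, 16, 17, 19, 20,
                                            21, 30, 39, 40, 43])
    def test_direct_patterns_need_no_postediting(self, pattern_id):
        assert asbru_model(pattern_id).needs_postediting == []

    def test_trigger_workaround_uses_auxiliary_variable(self):
        model = asbru_model(24)
        aux = model.aux_variables()
        assert "trigger_received" in aux
        target = model.plan("action_B")
        assert target.filter_precondition == "trigger_received"

    def test_free_condition_copied_verbatim_and_flagged(self):
        from conftest import make_process
        from cigflow.bpmn import SequenceFlow
        p = make_process(
            [("s", "start_event"), ("g1", "exclusive_gateway"), ("a", "task"),
             ("b", "task"), ("g2", "exclusive_gateway"), ("e", "end_event")],
            [("s", "g1"), ("g1", "a", "blood pressure still >140 mmHg"),
             ("g1", "b", 'not (condition="yes")'),
             ("a", "g2"), ("b", "g2"), ("g2", "e")],
        )
        model = transform_to_asbru(p)
        assert model.plan("a").filter_precondition == "blood pressure still >140 mmHg"
        assert any("verbatim" in reason for _, reason in model.needs_postediting)


class TestAsbruSerialization:
    def test_exclusive_choice_document(self):
        xml = serialize_asbru(asbru_model(4))
        assert 'type="any-order"' in xml
        assert "<wait-for>one</wait-for>" in xml
        assert xml.count("filter-precondition") >= 2

    def test_interleaved_routing_document(self):
        xml = serialize_asbru(asbru_model(40))
        assert 'type="any-order"' in xml
        assert "<wait-for>all</wait-for>" in xml

    def test_empty_model_refused(self):
        with pytest.raises(InvariantError, match="no plans"):
            serialize_asbru(AsbruModel([], "root"))

    def test_dangling_activation_refused(self):
        model = AsbruModel(
            [AsbruPlan("a", "sequentially", subplan_activations=("ghost",))], "a")
        with pytest.raises(InvariantError, match="ghost"):
            serialize_asbru(model)


class TestProformaMappings:
    def test_exclusive_choice_is_single_selection_decision(self):
        model = proforma_model(4)
        decisions = [t for t in model.tasks if t.kind == "decision"]
        assert len(decisions) == 1
        d = decisions[0]
        assert d.choice_mode == "single"
        assert len(d.candidates) == 2
        conditioned = [c for c in d.candidates if c.arguments]
        assert conditioned and conditioned[0].arguments[0][1] == 'condition="yes"'
        guarded = [t for t in model.tasks if t.candidate_of]
        assert {t.candidate_of[1] for t in guarded} == {c.name for c in d.candidates}

    def test_trigger_target_not_materialized_and_rerouted(self):
        model = proforma_model(24)
        names = {t.name for t in model.tasks}
        assert not any("msg" in n for n in names)  # no event component
        target = model.task("action_B")
        assert target.wait_condition == "completed(trigger_action)"
        assert "completed(action_A)" in target.scheduling_constraints

    def test_trigger_source_gets_event_trigger_with_message_start(self):
        model = proforma_model(24)
        assert model.task("trigger_action").event_trigger

    def test_transient_trigger_uses_event_trigger_on_target(self):
        model = proforma_model(23)
        target = model.task("action_B")
        assert target.event_trigger == "trigger_signal"
        assert target.wait_condition is None
        assert model.task("trigger_action").raises_event == "trigger_signal"

    def test_parallel_join_realized_by_constraints(self):
        from conftest import make_process
        p = make_process(
            [("s", "start_event"), ("g1", "parallel_gateway"),
             ("a", "task"), ("b", "task"), ("g2", "parallel_gateway"),
             ("c", "task"), ("e", "end_event")],
            [("s", "g1"), ("g1", "a"), ("g1", "b"), ("a", "g2"), ("b", "g2"),
             ("g2", "c"), ("c", "e")],
        )
        model = transform_to_proforma(p)
        # the post-join task awaits all branch tails (there is no join element)
        assert set(model.task("c").scheduling_constraints) == \
            {"completed(a)", "completed(b)"}

    @pytest.mark.parametrize("pattern_id", [17, 39, 40])
    def test_interleaving_patterns_not_implementable(self, pattern_id):
        with pytest.raises(NotImplementableError, match="proforma"):
            proforma_model(pattern_id)

    def test_multi_choice_flagged_for_postediting(self):
        model = proforma_model(6)
        d = next(t for t in model.tasks if t.kind == "decision")
        assert d.choice_mode == "multiple"
        assert model.needs_postediting

    def test_milestone_is_direct_precondition(self):
        model = proforma_model(18)
        assert model.task("action_B").precondition == "milestone_holds"
        assert model.needs_postediting == []


class TestProformaSerialization:
    def test_sequence_constraints(self):
        text = serialize_proforma(proforma_model(1))
        assert "schedule_constraint : completed(action_A)" in text

    def test_trigger_document_has_wait_condition(self):
        text = serialize_proforma(proforma_model(24))
        block = text.split("action :: 'action_B'")[1].split("end action.")[0]
        assert "wait_condition : completed(trigger_action)" in block

    def test_cyclic_constraints_refused(self):
        model = ProformaModel(
            [ProformaTask("a", "action", scheduling_constraints=("completed(b)",)),
             ProformaTask("b", "action", scheduling_constraints=("completed(a)",)),
             ProformaTask("root", "plan", components=("a", "b"))],
            "root")
        with pytest.raises(InvariantError, match="cyclic"):
            serialize_proforma(model)

    def test_dangling_constraint_refused(self):
        model = ProformaModel(
            [ProformaTask("a", "action", scheduling_constraints=("completed(x)",)),
             ProformaTask("root", "plan", components=("a",))],
            "root")
        with pytest.raises(InvariantError, match="dangling"):
            serialize_proforma(model)


class TestImplementabilityMatrixConformance:
    """Emitters refuse exactly the '-' cells of the implementability matrix."""

    @pytest.mark.parametrize("pattern_id",
                             [p.id for p in catalog.relevant_patterns()])
    @pytest.mark.parametrize("language", ["asbru", "proforma"])
    def test_refusal_matches_matrix(self, pattern_id, language):
        transform = transform_to_asbru if language == "asbru" \
            else transform_to_proforma
        label = catalog.implementability(pattern_id, language).label
        process = generate_fixture(FixtureSpec(pattern_id))
        if label == "not_implementable":
            with pytest.raises(NotImplementableError):
                transform(process)
        else:
            transform(process)  # must not raise
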