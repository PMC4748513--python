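"""BPMN reader/writer and structuredness validation."""

import networkx as nx
import pytest

from cigflow import (
    FixtureSpec, generate_composition, generate_fixture, parse_bpmn,
    serialize_bpmn, validate_structuredness,
)
from cigflow.bpmn import BpmnProcess, FlowNode, GATEWAY_KINDS, SequenceFlow
from cigflow.errors import BpmnParseError, InvariantError, UnsupportedConstructError

from conftest import RELEVANT_IDS, make_process


MINIMAL = """
<bpmn:definitions xmlns:bpmn="http://www.omg.org/spec/BPMN/20100524/MODEL">
  <bpmn:process id="p">
    <bpmn:startEvent id="s"/>
    <bpmn:task id="a" name="A"/>
    <bpmn:task id="b" name="B"/>
    <bpmn:endEvent id="e"/>
    <bpmn:sequenceFlow id="f1" sourceRef="s" targetRef="a"/>
    <bpmn:sequenceFlow id="f2" sourceRef="a" targetRef="b"/>
    <bpmn:sequenceFlow id="f3" sourceRef="b" targetRef="e"/>
  </bpmn:process>
</bpmn:definitions>
"""


def processes_isomorphic(p1: BpmnProcess, p2: BpmnProcess) -> bool:
    def node_key(n: FlowNode):
        return (n.node_id, n.kind, n.name, n.ordering, n.completion_condition,
                n.pattern_annotation, n.persistent, n.quorum,
                tuple(sorted(c.node_id for c in n.children)))

    def keys(p: BpmnProcess):
        return (
            sorted(node_key(n) for n in p.all_nodes()),
            sorted((f.source, f.target, f.condition, f.is_default) for f in p.flows),
            sorted((t.event, t.source) for t in p.triggers),
        )

    return keys(p1) == keys(p2)


class TestParse:
    def test_minimal_sequence(self):
        p = parse_bpmn(MINIMAL)
        assert len(p.nodes) == 4 and len(p.flows) == 3
        assert p.node("a").kind == "task" and p.node("a").name == "A"

    def test_exclusive_choice_fixture(self):
        p = parse_bpmn(serialize_bpmn(generate_fixture(FixtureSpec(4))))
        gateways = [n for n in p.nodes if n.kind == "exclusive_gateway"]
        conditioned = [f for f in p.flows if f.condition]
        assert len(gateways) == 2
        assert len(conditioned) == 2

    def test_malformed_xml_reports_parse_error(self):
        with pytest.raises(BpmnParseError, match="malformed"):
            parse_bpmn("<bpmn:definitions><unclosed>")

    def test_timer_event_is_unsupported(self):
        doc = MINIMAL.replace(
            '<bpmn:startEvent id="s"/>',
            '<bpmn:startEvent id="s">'
            "<bpmn:timerEventDefinition/></bpmn:startEvent>",
        )
        with pytest.raises(UnsupportedConstructError, match="timerEventDefinition"):
            parse_bpmn(doc)

    def test_unknown_element_is_unsupported(self):
        doc = MINIMAL.replace('<bpmn:task id="a" name="A"/>',
                              '<bpmn:task id="a" name="A"/><bpmn:dataObject id="d"/>')
        with pytest.raises(UnsupportedConstructError, match="dataObject"):
            parse_bpmn(doc)

    def test_any_namespace_prefix_is_accepted(self):
        doc = MINIMAL.replace("bpmn:", "x:").replace(
            "xmlns:bpmn=", "xmlns:x=")
        p = parse_bpmn(doc)
        assert len(p.nodes) == 4

    def test_trigger_accepted_as_message_flow(self):
        xml = serialize_bpmn(generate_fixture(FixtureSpec(24)))
        xml = xml.replace("<bpmn:association",
                          "<bpmn:association").replace("association", "messageFlow")
        p = parse_bpmn(xml)
        assert p.triggers and p.triggers[0].source == "p24_trigger_action"


class TestSerialize:
    @pytest.mark.parametrize("pattern_id", RELEVANT_IDS)
    def test_roundtrip_is_isomorphic(self, pattern_id):
        p = generate_fixture(FixtureSpec(pattern_id))
        assert processes_isomorphic(parse_bpmn(serialize_bpmn(p)), p)

    def test_adhoc_ordering_and_completion_condition(self):
        xml = serialize_bpmn(generate_fixture(FixtureSpec(40)))
        assert 'ordering="sequential"' in xml
        assert "completionCondition" in xml

    def test_duplicate_ids_refused(self):
        p = make_process([("a", "task"), ("a", "task")], [])
        with pytest.raises(InvariantError, match="duplicate"):
            serialize_bpmn(p)

    def test_default_flow_roundtrip(self):
        p = make_process(
            [("s", "start_event"), ("g1", "exclusive_gateway"), ("a", "task"),
             ("b", "task"), ("g2", "exclusive_gateway"), ("e", "end_event")],
            [("s", "g1"), ("g1", "a", 'c="1"'), ("a", "g2"), ("b", "g2"),
             ("g2", "e")],
        )
        p.flows.append(SequenceFlow("fd", "g1", "b", None, is_default=True))
        p2 = parse_bpmn(serialize_bpmn(p))
        assert [f.flow_id for f in p2.flows if f.is_default] == ["fd"]


# ---------------------------------------------------------------------------
# structuredness


def oracle_structured(process: BpmnProcess):
    """Brute-force split-join pairing oracle for small acyclic models.

    For every split gateway, its join must be the unique first node shared
    by all outgoing paths, of the same gateway kind, and the node set
    strictly between split and join must have no edges crossing the region
    boundary.  Independent of the recursive-descent implementation.
    """
    g = process.graph()
    for node in process.nodes:
        if node.kind not in GATEWAY_KINDS or g.out_degree(node.node_id) <= 1:
            continue
        sinks = [n for n in g if g.out_degree(n) == 0]
        paths = [p for sink in sinks
                 for p in nx.all_simple_paths(g, node.node_id, sink)]
        common = set(paths[0][1:])
        for p in paths[1:]:
            common &= set(p[1:])
        ordered = [n for n in paths[0] if n in common]
        if not ordered:
            return False
        join = ordered[0]
        expected = ("exclusive_gateway" if node.kind == "event_based_gateway"
                    else node.kind)
        if process.node(join).kind != expected:
            return False
        interior = {n for p in paths for n in p[1:p.index(join)]}
        for n in interior:
            if any(u not in interior | {node.node_id} for u in g.predecessors(n)):
                return False
            if any(v not in interior | {join} for v in g.successors(n)):
                return False
    return True


class TestStructuredness:
    @pytest.mark.parametrize("pattern_id", RELEVANT_IDS)
    def test_all_fixtures_are_structured(self, pattern_id):
        report = validate_structuredness(generate_fixture(FixtureSpec(pattern_id)))
        assert report.structured and not report.violations

    def test_kind_mismatch_is_reported(self, and_xor_mismatch):
        assert not oracle_structured(and_xor_mismatch)
        report = validate_structuredness(and_xor_mismatch)
        assert not report.structured
        assert any("kind mismatch" in reason for _, reason in report.violations)

    def test_overlapping_regions_are_reported(self, overlapping_regions):
        assert not oracle_structured(overlapping_regions)
        report = validate_structuredness(overlapping_regions)
        assert not report.structured
        assert any("incoming" in r or "outgoing" in r or "nesting" in r
                   for _, r in report.violations)

    def test_oracle_agrees_on_structured_models(self):
        # acyclic, trigger-free fixtures, where the oracle is applicable
        for pid in (1, 2, 4, 6, 9, 16, 30, 39, 43):
            process = generate_fixture(FixtureSpec(pid))
            assert oracle_structured(process)
            assert validate_structuredness(process).structured

    def test_composition_remains_structured(self):
        process = generate_composition(
            [FixtureSpec(1), FixtureSpec(4), FixtureSpec(2)], seed=5)
        assert validate_structuredness(process).structured
        assert oracle_structured(process)
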