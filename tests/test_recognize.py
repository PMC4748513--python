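"""Region decomposition and pattern detection."""

import networkx as nx
import pytest

from cigflow import (
    FixtureSpec, decompose, detect_patterns, generate_composition,
    generate_fixture, parse_bpmn, serialize_bpmn,
)
from cigflow.errors import StructurednessError
from cigflow.recognize import top_instance

from conftest import RELEVANT_IDS


def sese_oracle(process, region):
    """Brute-force single-entry/single-exit check for an acyclic region:
    no edge crosses the member boundary except through entry and exit."""
    g = process.graph()
    members = {m for m in region.members if m in g}
    for m in members:
        for u in g.predecessors(m):
            if u not in members and m != region.entry:
                return False
        for v in g.successors(m):
            if v not in members and m != region.exit:
                return False
    return True


class TestDecompose:
    def test_sequence_fixture_has_leaf_children(self):
        p = generate_fixture(FixtureSpec(1))
        root = decompose(p)
        assert root.kind == "sequence"
        assert all(c.kind == "leaf" for c in root.children)
        assert root.members == {n.node_id for n in p.nodes}

    def test_composition_nests_choice_inside_sequence(self):
        p = generate_composition([FixtureSpec(1), FixtureSpec(4)], seed=0)
        root = decompose(p)
        assert root.kind == "sequence"
        blocks = [c for c in root.children if c.kind == "block"]
        assert len(blocks) == 1
        assert blocks[0].meta["split_kind"] == "exclusive_gateway"
        assert sese_oracle(p, blocks[0])

    def test_unstructured_model_raises_with_report(self, and_xor_mismatch):
        with pytest.raises(StructurednessError) as exc:
            decompose(and_xor_mismatch)
        assert exc.value.report.violations

    @pytest.mark.parametrize("pattern_id", [1, 2, 4, 6, 16, 21, 25, 40, 43])
    def test_members_cover_all_nodes(self, pattern_id):
        p = generate_fixture(FixtureSpec(pattern_id))
        root = decompose(p)
        assert root.members == {n.node_id for n in p.all_nodes()}

    def test_sibling_leaves_partition_members(self):
        p = generate_composition([FixtureSpec(1), FixtureSpec(2)], seed=1)
        root = decompose(p)

        def leaves(region):
            if not region.children:
                return [region]
            out = []
            for c in region.children:
                out.extend(leaves(c))
            return out

        leaf_sets = [l.members for l in leaves(root)]
        covered = set().union(*leaf_sets)
        # every top-level node appears in exactly one leaf
        assert sum(len(s) for s in leaf_sets) == len(covered)
        assert {n.node_id for n in p.nodes} <= covered | root.members


class TestDetectPatterns:
    @pytest.mark.parametrize("pattern_id", RELEVANT_IDS)
    def test_generator_recognizer_inverse(self, pattern_id):
        """The fixture of every relevant pattern is recognized as exactly
        that pattern at the whole-process region."""
        p = generate_fixture(FixtureSpec(pattern_id))
        top = top_instance(p)
        assert top is not None
        assert pattern_id in top.pattern_ids

    def test_plain_sequence_yields_only_sequence(self):
        instances = detect_patterns(generate_fixture(FixtureSpec(1)))
        assert [i.pattern_ids for i in instances] == [(1,)]

    def test_trigger_roles(self):
        p = generate_fixture(FixtureSpec(24))
        top = top_instance(p)
        assert top.roles["trigger_source"] == "p24_trigger_action"
        assert top.roles["target"] == "p24_action_B"

    def test_interleaved_routing_roles(self):
        p = generate_fixture(FixtureSpec(40, branch_count=3))
        top = top_instance(p)
        branch_roles = [k for k in top.roles if k.startswith("branch_")]
        assert len(branch_roles) == 3

    def test_split_join_pairs_report_both_ids(self):
        for pid, ids in [(2, (2, 3)), (4, (4, 5)), (6, (6, 7))]:
            top = top_instance(generate_fixture(FixtureSpec(pid)))
            assert top.pattern_ids == ids

    def test_deterministic_across_reparse(self):
        p = generate_composition([FixtureSpec(1), FixtureSpec(4)], seed=2)
        xml = serialize_bpmn(p)
        first = [(i.pattern_ids, i.region.entry, i.roles)
                 for i in detect_patterns(parse_bpmn(xml))]
        second = [(i.pattern_ids, i.region.entry, i.roles)
                  for i in detect_patterns(parse_bpmn(xml))]
        assert first == second

    def test_composition_reports_outer_and_inner(self):
        p = generate_composition([FixtureSpec(1), FixtureSpec(4)], seed=0)
        ids = [i.pattern_ids for i in detect_patterns(p)]
        assert (1,) in ids and (4, 5) in ids

    def test_roles_reference_member_nodes(self):
        for pid in RELEVANT_IDS:
            p = generate_fixture(FixtureSpec(pid))
            for inst in detect_patterns(p):
                members = inst.region.members
                for role, value in inst.roles.items():
                    if role == "quorum":
                        continue
                    assert value in members, (pid, role, value)
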