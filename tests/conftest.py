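import pytest
from hypothesis import settings

from cigflow import FixtureSpec, relevant_patterns

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from cigflow.bpmn import BpmnProcess, FlowNode, SequenceFlow

RELEVANT_IDS = [p.id for p in relevant_patterns()]


@pytest.fixture(scope="session")
def relevant_ids() -> list[int]:
    return list(RELEVANT_IDS)


def make_process(nodes, flows, process_id="test", triggers=()):
    """Terse constructor for hand-built processes in tests.

    ``nodes``: list of (id, kind) or (id, kind, extra-kwargs) tuples;
    ``flows``: list of (source, target) or (source, target, condition).
    """
    built_nodes = []
    for spec in nodes:
        node_id, kind, *rest = spec
        built_nodes.append(FlowNode(node_id, kind, **(rest[0] if rest else {})))
    built_flows = []
    for i, spec in enumerate(flows):
        src, dst, *rest = spec
        built_flows.append(SequenceFlow(f"f{i}", src, dst,
                                        condition=rest[0] if rest else None))
    return BpmnProcess(process_id, built_nodes, built_flows, list(triggers))


@pytest.fixture
def and_xor_mismatch():
    """Six-node model whose AND split is closed by an XOR join."""
    return make_process(
        [("s", "start_event"), ("g1", "parallel_gateway"),
         ("a", "task"), ("b", "task"),
         ("g2", "exclusive_gateway"), ("e", "end_event")],
        [("s", "g1"), ("g1", "a"), ("g1", "b"), ("a", "g2"), ("b", "g2"),
         ("g2", "e")],
    )


@pytest.fixture
def overlapping_regions():
    """A flow escapes one branch of a split-join region past its join."""
    return make_process(
        [("s", "start_event"), ("g1", "exclusive_gateway"),
         ("a", "task"), ("b", "task"),
         ("g2", "exclusive_gateway"), ("c", "task"), ("e", "end_event")],
        [("s", "g1"), ("g1", "a", 'x="1"'), ("g1", "b", 'x="2"'),
         ("a", "g2"), ("b", "g2"), ("g2", "c"), ("a", "c"), ("c", "e")],
    )
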