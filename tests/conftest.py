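from __future__ import annotations

import pytest

from logicpath.logic_network import (
    EdgeRecord,
    Logic,
    LogicNetwork,
    NodeRecord,
    Polarity,
)


def make_net(edge_specs, nodes=None) -> LogicNetwork:
    """Build a network from (src, dst, '+'/'-', 'AND'/'OR') tuples."""
    edges = [
        EdgeRecord(src, dst,
                   Polarity.POSITIVE if pol == "+" else Polarity.NEGATIVE,
                   Logic(logic))
        for src, dst, pol, logic in edge_specs
    ]
    node_records = [NodeRecord(id=n) for n in (nodes or [])]
    return LogicNetwork(node_records, edges)


@pytest.fixture
def chain_net() -> LogicNetwork:
    """A -> B -> C with one negative edge."""
    return make_net([("A", "B", "+", "AND"), ("B", "C", "-", "AND")])


@pytest.fixture
def diamond_net() -> LogicNetwork:
    """A -> {B, C} -> D, the B arm negative."""
    return make_net([
        ("A", "B", "-", "AND"),
        ("A", "C", "+", "AND"),
        ("B", "D", "+", "AND"),
        ("C", "D", "+", "AND"),
    ])
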