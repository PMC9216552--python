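"""Path-parity prediction of perturbation effects.

Automates the manual inspection procedure: enumerate the simple directed
paths from a root input to a key output and vote over their parities.  A
path with an even number of inhibitory edges transmits the perturbation
direction unchanged; odd parity inverts it; no path, or a tie between even
and odd paths, yields no change.  Edge AND/OR logic is deliberately ignored
here — only polarity matters for these rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .logic_network import (
    Direction,
    LogicNetwork,
    OutcomeClass,
    TestCase,
    ValidationError,
)

__all__ = [
    "PathRecord",
    "PathEnumeration",
    "CuratorPrediction",
    "enumerate_paths",
    "predict_curator",
    "path_length_summary",
    "DEFAULT_MAX_PATHS",
    "DEFAULT_MAX_LEN",
]

# observed pathway path lengths top out in the mid-forties, so a length cap
# of 50 is lossless in practice; the path-count cap guards dense graphs
DEFAULT_MAX_LEN = 50
DEFAULT_MAX_PATHS = 10_000


@dataclass(frozen=True)
class PathRecord:
    nodes: tuple[str, ...]
    negative_edge_count: int

    @property
    def parity(self) -> str:
        return "odd" if self.negative_edge_count % 2 else "even"

    @property
    def length(self) -> int:
        return len(self.nodes) - 1


@dataclass
class PathEnumeration:
    paths: list[PathRecord] = field(default_factory=list)
    truncated: bool = False

    def parity_counts(self) -> tuple[int, int]:
        """(even, odd) path counts."""
        odd = sum(1 for p in self.paths if p.parity == "odd")
        return len(self.paths) - odd, odd


@dataclass
class CuratorPrediction:
    predicted_class: OutcomeClass
    n_even_paths: int
    n_odd_paths: int
    low_confidence: bool = False


def enumerate_paths(net: LogicNetwork, src: str, dst: str,
                    max_paths: int = DEFAULT_MAX_PATHS,
                    max_len: int = DEFAULT_MAX_LEN) -> PathEnumeration:
    """All simple directed paths from *src* to *dst*, with negative-edge
    counts, in lexicographic node-sequence order.

    Parallel edges of opposite polarity yield distinct path records over the
    same node sequence.  If either cap is hit, ``truncated`` is set rather
    than failing or silently dropping paths.
    """
    for n in (src, dst):
        if n not in net.nodes:
            raise ValidationError(f"node {n!r} not in network")
    g = net.to_multidigraph()
    result = PathEnumeration()
    if src == dst:
        return result
    explored = 0
    for edge_path in nx.all_simple_edge_paths(g, src, dst):
        explored += 1
        if explored > max_paths:
            result.truncated = True
            break
        if len(edge_path) > max_len:
            result.truncated = True  # over-length path exists but is dropped
            continue
        neg = sum(1 for (u, v, k) in edge_path if g.edges[u, v, k]["negative"])
        nodes = (src,) + tuple(v for (_, v, _) in edge_path)
        result.paths.append(PathRecord(nodes=nodes, negative_edge_count=neg))
    result.paths.sort(key=lambda p: (p.nodes, p.negative_edge_count))
    return result


def predict_curator(net: LogicNetwork, case: TestCase,
                    max_paths: int = DEFAULT_MAX_PATHS,
                    max_len: int = DEFAULT_MAX_LEN) -> CuratorPrediction:
    """Apply the parity/majority rules to one test case.

    Majority of even-parity paths: key output moves in the same direction as
    the root perturbation.  Majority odd: opposite direction.  No path, or an
    exact even/odd tie (opposing-polarity cancellation): no change.
    """
    enum = enumerate_paths(net, case.root_input, case.key_output,
                           max_paths=max_paths, max_len=max_len)
    even, odd = enum.parity_counts()
    if even > odd:
        predicted = (OutcomeClass.UP if case.direction is Direction.UP
                     else OutcomeClass.DOWN)
    elif odd > even:
        predicted = (OutcomeClass.DOWN if case.direction is Direction.UP
                     else OutcomeClass.UP)
    else:
        predicted = OutcomeClass.NO_CHANGE
    return CuratorPrediction(predicted_class=predicted,
                             n_even_paths=even, n_odd_paths=odd,
                             low_confidence=enum.truncated)


def path_length_summary(net: LogicNetwork,
                        cases: list[TestCase]) -> dict[str, int | None]:
    """Shortest directed path length (edge count) per case; ``None`` when the
    key output is unreachable from the root input."""
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((e.source, e.target) for e in net.edges)
    out: dict[str, int | None] = {}
    lengths_cache: dict[str, dict[str, int]] = {}
    for case in cases:
        src = case.root_input
        if src not in lengths_cache:
            lengths_cache[src] = nx.single_source_shortest_path_length(g, src)
        out[case.case_id()] = lengths_cache[src].get(case.key_output)
    return out
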