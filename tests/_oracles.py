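"""Independent oracles used by the test suite.

Deliberately naive and written against the raw data model rather than the
production code paths they check.
"""

from __future__ import annotations

import math

from logicpath.logic_network import LogicNetwork


def topological_order(net: LogicNetwork) -> list[str]:
    """Kahn's algorithm over the raw edge list (fails on cycles)."""
    in_deg = {n: 0 for n in net.nodes}
    children: dict[str, list[str]] = {n: [] for n in net.nodes}
    for e in net.edges:
        in_deg[e.target] += 1
        children[e.source].append(e.target)
    frontier = sorted(n for n, d in in_deg.items() if d == 0)
    order: list[str] = []
    while frontier:
        node = frontier.pop(0)
        order.append(node)
        for child in children[node]:
            in_deg[child] -= 1
            if in_deg[child] == 0:
                frontier.append(child)
        frontier.sort()
    assert len(order) == len(net.nodes), "cycle detected"
    return order


def closed_form_pure_and(net: LogicNetwork, fixed: dict[str, float],
                         lower: float, upper: float) -> dict[str, float]:
    """Clamped product propagation for acyclic pure-AND networks.

    ``fixed`` maps root ids to raw activity values; every in-degree-0 node
    must be covered.  Returns raw activities per node.
    """
    log_lb, log_ub = math.log10(lower), math.log10(upper)
    by_target: dict[str, list[tuple[str, int]]] = {}
    for e in net.edges:
        by_target.setdefault(e.target, []).append(
            (e.source, -1 if e.is_negative else 1))
    val: dict[str, float] = {}
    for node in topological_order(net):
        if node not in by_target:
            val[node] = math.log10(fixed[node])
            continue
        total = sum(sign * val[src] for src, sign in by_target[node])
        val[node] = min(max(total, log_lb), log_ub)
    return {n: 10.0 ** v for n, v in val.items()}


# nine-entry lookup, spelled out so it cannot share a code path with the
# production categorizer
CONFUSION_TABLE = {
    ("up", "up"): "TP",
    ("down", "down"): "TP",
    ("up", "down"): "FP-WD",
    ("down", "up"): "FP-WD",
    ("up", "no_change"): "FP",
    ("down", "no_change"): "FP",
    ("no_change", "up"): "FN",
    ("no_change", "down"): "FN",
    ("no_change", "no_change"): "TN",
}


def confusion_counts(pairs: list[tuple[str, str]]) -> dict[str, int]:
    counts = {"TP": 0, "TN": 0, "FP": 0, "FP-WD": 0, "FN": 0}
    for predicted, observed in pairs:
        counts[CONFUSION_TABLE[(predicted, observed)]] += 1
    return counts
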