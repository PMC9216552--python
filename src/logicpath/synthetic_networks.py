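"""Seeded generators of logic networks with known ground truth.

Networks are layered DAGs with configurable negative-edge and OR-gate
probabilities, layer-skipping edges, OR fan-in emulating entity sets, and
optional feedback edges.  Ground-truth outcome classes for test cases are
computed by a deliberately naive exhaustive path enumerator that shares no
code with the production predictors, so it can serve as an independent
oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .logic_network import (
    Direction,
    EdgeRecord,
    EntityClass,
    Logic,
    LogicNetwork,
    NodeRecord,
    NodeRole,
    OutcomeClass,
    Polarity,
    TestCase,
    enumerate_test_cases,
    infer_roles,
)

__all__ = ["GeneratorConfig", "ConfigError", "generate_network",
           "generate_ground_truth_cases"]


class ConfigError(ValueError):
    """Raised for unsatisfiable generator configurations."""


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_layers: int = 4
    layer_width: int = 4
    p_negative: float = 0.25
    p_or: float = 0.3
    p_skip: float = 0.1
    p_cycle: float = 0.0
    set_fan_in: int = 3

    def validate(self) -> None:
        if self.n_layers < 2:
            raise ConfigError("need at least 2 layers to place any edge")
        if self.layer_width < 1:
            raise ConfigError("layer width must be >= 1")
        for name in ("p_negative", "p_or", "p_skip", "p_cycle"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.set_fan_in < 1:
            raise ConfigError("set_fan_in must be >= 1")


_ROOT_CLASSES = [EntityClass.PROTEIN, EntityClass.GENE, EntityClass.RNA]
_INNER_CLASSES = [EntityClass.PROTEIN, EntityClass.COMPLEX,
                  EntityClass.RNA, EntityClass.REACTION]
_LEAF_CLASSES = [EntityClass.PROTEIN, EntityClass.COMPLEX,
                 EntityClass.POLYMER, EntityClass.SMALL_MOLECULE]


def generate_network(
        cfg: GeneratorConfig,
        layer_widths: list[int] | None = None,
) -> tuple[LogicNetwork, list[NodeRole]]:
    """Generate a weakly connected layered network with >=1 root input and
    >=1 terminal output.  Identical configs produce identical networks.

    *layer_widths* overrides ``cfg.layer_width`` with an explicit per-layer
    width list (its length then defines the number of layers).
    """
    cfg.validate()
    if layer_widths is None:
        layer_widths = [cfg.layer_width] * cfg.n_layers
    if len(layer_widths) < 2 or any(w < 1 for w in layer_widths):
        raise ConfigError("layer_widths needs >=2 layers of width >=1")
    rng = np.random.default_rng(cfg.seed)
    n_layers = len(layer_widths)

    layer_of: dict[str, int] = {}
    layers: list[list[str]] = []
    for li, width in enumerate(layer_widths):
        ids = [f"N{li:02d}_{i:02d}" for i in range(width)]
        layers.append(ids)
        for nid in ids:
            layer_of[nid] = li

    node_logic: dict[str, Logic] = {}
    edges: list[EdgeRecord] = []

    def polarity() -> Polarity:
        return (Polarity.NEGATIVE if rng.random() < cfg.p_negative
                else Polarity.POSITIVE)

    for li in range(1, n_layers):
        for nid in layers[li]:
            logic = Logic.OR if rng.random() < cfg.p_or else Logic.AND
            node_logic[nid] = logic
            if logic is Logic.OR:
                k = int(rng.integers(2, max(cfg.set_fan_in, 2) + 1))
            else:
                k = int(rng.integers(1, 3))
            pool = list(layers[li - 1])
            if li > 1 and rng.random() < cfg.p_skip:
                skip_layer = int(rng.integers(0, li - 1))
                pool += layers[skip_layer]
            k = min(k, len(pool))
            parents = rng.choice(pool, size=k, replace=False)
            for p in parents:
                edges.append(EdgeRecord(str(p), nid, polarity(), logic))

    # every node below the last layer must feed something downstream
    have_child = {e.source for e in edges}
    for li in range(n_layers - 1):
        for nid in layers[li]:
            if nid not in have_child:
                child = str(rng.choice(layers[li + 1]))
                edges.append(EdgeRecord(nid, child, polarity(),
                                        node_logic[child]))
                have_child.add(nid)

    # feedback edges run from an intermediate layer back to an earlier
    # non-root node; last-layer nodes are never sources, so terminal outputs
    # survive, and roots are never targets
    if cfg.p_cycle > 0 and n_layers >= 3:
        for li in range(1, n_layers - 1):
            for nid in layers[li]:
                if rng.random() < cfg.p_cycle:
                    tgt_layer = int(rng.integers(1, li + 1))
                    candidates = [t for t in layers[tgt_layer] if t != nid]
                    if not candidates:
                        continue
                    tgt = str(rng.choice(candidates))
                    edges.append(EdgeRecord(nid, tgt, polarity(),
                                            node_logic[tgt]))

    # stitch weakly connected components together, always wiring from a
    # lower layer into a higher one so the layered structure is preserved
    comps = _weak_components(list(layer_of), edges)
    while len(comps) > 1:
        comps.sort(key=lambda c: min(c))
        a, b = comps[0], comps[1]
        pair = min(
            ((u, v) for u in a for v in b if layer_of[u] < layer_of[v]),
            default=None)
        if pair is None:
            pair = min((u, v) for u in b for v in a if layer_of[u] < layer_of[v])
        u, v = pair
        edges.append(EdgeRecord(u, v, polarity(), node_logic[v]))
        comps = _weak_components(list(layer_of), edges)

    nodes = []
    fan_in: dict[str, int] = {}
    for e in edges:
        fan_in[e.target] = fan_in.get(e.target, 0) + 1
    for li, ids in enumerate(layers):
        for nid in ids:
            if li == 0:
                cls = _ROOT_CLASSES[int(rng.integers(len(_ROOT_CLASSES)))]
            elif (node_logic.get(nid) is Logic.OR
                  and fan_in.get(nid, 0) >= 2):
                cls = EntityClass.SET
            elif li == len(layers) - 1:
                cls = _LEAF_CLASSES[int(rng.integers(len(_LEAF_CLASSES)))]
            else:
                cls = _INNER_CLASSES[int(rng.integers(len(_INNER_CLASSES)))]
            nodes.append(NodeRecord(id=nid, name=nid.replace("_", " "),
                                    entity_class=cls))

    net = LogicNetwork(nodes, edges)
    net.validate()
    roles = infer_roles(net)
    if not any(r.is_root_input for r in roles):
        raise ConfigError("generated network has no root input")
    if not any(r.is_terminal_output for r in roles):
        raise ConfigError("generated network has no terminal output")
    return net, roles


def _weak_components(nodes: list[str],
                     edges: list[EdgeRecord]) -> list[set[str]]:
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        ra, rb = find(e.source), find(e.target)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, set[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return list(comps.values())


# ---------------------------------------------------------------------------
# Independent brute-force ground truth
# ---------------------------------------------------------------------------

def _all_path_parities(net: LogicNetwork, src: str, dst: str) -> list[int]:
    """Parities (0 even / 1 odd) of every simple directed path src->dst,
    by plain recursive DFS over the raw edge list.  Exponential on purpose;
    intended for small networks only."""
    adj: dict[str, list[tuple[str, int]]] = {}
    for e in net.edges:
        adj.setdefault(e.source, []).append(
            (e.target, 1 if e.is_negative else 0))
    parities: list[int] = []

    def dfs(node: str, neg: int, visited: set[str]) -> None:
        if node == dst:
            parities.append(neg % 2)
            return
        for child, w in adj.get(node, []):
            if child not in visited:
                visited.add(child)
                dfs(child, neg + w, visited)
                visited.remove(child)

    if src != dst:
        dfs(src, 0, {src})
    return parities


def generate_ground_truth_cases(
        net: LogicNetwork, roles: list[NodeRole]) -> list[TestCase]:
    """Bidirectional test cases for every (root input, key output) pair with
    observed classes filled in by the brute-force parity oracle: majority of
    even-parity paths transmits the root direction, majority odd inverts it,
    no path or a tie means no change."""
    roots = [r.node_id for r in roles if r.is_root_input]
    kos = [r.node_id for r in roles if r.is_key_output and not r.is_root_input]
    cases = enumerate_test_cases(net, roots, kos)
    parity_cache: dict[tuple[str, str], list[int]] = {}
    for case in cases:
        key = (case.root_input, case.key_output)
        if key not in parity_cache:
            parity_cache[key] = _all_path_parities(net, *key)
        parities = parity_cache[key]
        n_odd = sum(parities)
        n_even = len(parities) - n_odd
        if n_even > n_odd:
            observed = (OutcomeClass.UP if case.direction is Direction.UP
                        else OutcomeClass.DOWN)
        elif n_odd > n_even:
            observed = (OutcomeClass.DOWN if case.direction is Direction.UP
                        else OutcomeClass.UP)
        else:
            observed = OutcomeClass.NO_CHANGE
        case.observed_class = observed
    return cases
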