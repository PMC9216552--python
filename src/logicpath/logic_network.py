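"""Data model, validation, I/O and graph queries for logic networks.

A logic network is a signed directed graph in which every edge carries a
polarity (activating ``+`` or inhibiting ``-``) and a logic class (``AND`` or
``OR``) describing how the target node combines its inputs.  Root inputs are
nodes that are never produced inside the network (in-degree 0); terminal
outputs are nodes that are never consumed (out-degree 0).
"""

from __future__ import annotations

import enum
import io
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "EntityClass",
    "Polarity",
    "Logic",
    "Direction",
    "OutcomeClass",
    "NodeRecord",
    "EdgeRecord",
    "NodeRole",
    "TestCase",
    "LogicNetwork",
    "FormatError",
    "ValidationError",
    "read_logic_table",
    "write_logic_table",
    "infer_roles",
    "enumerate_test_cases",
]


class FormatError(ValueError):
    """Raised when a logic-table file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


class EntityClass(str, enum.Enum):
    PROTEIN = "protein"
    GENE = "gene"
    RNA = "rna"
    COMPLEX = "complex"
    SET = "set"
    SMALL_MOLECULE = "small_molecule"
    POLYMER = "polymer"
    REACTION = "reaction"
    AUXILIARY = "auxiliary"


class Polarity(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"

    @property
    def symbol(self) -> str:
        return "+" if self is Polarity.POSITIVE else "-"


class Logic(str, enum.Enum):
    AND = "AND"
    OR = "OR"


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"

    def flipped(self) -> "Direction":
        return Direction.DOWN if self is Direction.UP else Direction.UP


class OutcomeClass(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    NO_CHANGE = "no_change"

    @property
    def is_change(self) -> bool:
        return self is not OutcomeClass.NO_CHANGE

    def flipped(self) -> "OutcomeClass":
        if self is OutcomeClass.UP:
            return OutcomeClass.DOWN
        if self is OutcomeClass.DOWN:
            return OutcomeClass.UP
        return self


@dataclass(frozen=True)
class NodeRecord:
    id: str
    name: str = ""
    entity_class: EntityClass = EntityClass.AUXILIARY

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("node id must be a non-empty string")
        if not self.name:
            object.__setattr__(self, "name", self.id)


@dataclass(frozen=True)
class EdgeRecord:
    source: str
    target: str
    polarity: Polarity
    logic: Logic

    @property
    def is_negative(self) -> bool:
        return self.polarity is Polarity.NEGATIVE

    def key(self) -> tuple[str, str, Polarity]:
        # dedup key: same (source, target, polarity) with differing logic is
        # still the same physical edge
        return (self.source, self.target, self.polarity)


@dataclass(frozen=True)
class NodeRole:
    node_id: str
    is_root_input: bool = False
    is_terminal_output: bool = False
    is_key_output: bool = False


@dataclass
class TestCase:
    """One (root input, direction, key output) perturbation scenario."""

    __test__ = False  # not a pytest class despite the name

    root_input: str
    direction: Direction
    key_output: str
    predicted_class: OutcomeClass | None = None
    observed_class: OutcomeClass | None = None
    pathway: str | None = None

    def case_id(self) -> str:
        return f"{self.root_input}|{self.direction.value}|{self.key_output}"


class LogicNetwork:
    """Signed directed graph with per-node input-combination logic.

    Exact duplicate edges are collapsed on construction; a pair of edges with
    the same endpoints but opposite polarity is kept (dual regulation).
    Cycles are permitted.
    """

    def __init__(
        self,
        nodes: Iterable[NodeRecord] = (),
        edges: Iterable[EdgeRecord] = (),
        *,
        strict_nodes: bool = False,
    ) -> None:
        self.nodes: dict[str, NodeRecord] = {}
        for rec in nodes:
            if rec.id in self.nodes:
                raise ValidationError(f"duplicate node id {rec.id!r}")
            self.nodes[rec.id] = rec

        self.edges: list[EdgeRecord] = []
        seen: dict[tuple[str, str, Polarity], EdgeRecord] = {}
        undeclared: list[str] = []
        for e in edges:
            prev = seen.get(e.key())
            if prev is not None:
                if prev.logic is not e.logic:
                    logger.warning(
                        "conflicting logic for duplicate edge %s->%s (%s); "
                        "keeping %s", e.source, e.target, e.polarity.symbol,
                        prev.logic.value)
                else:
                    logger.info(
                        "collapsing duplicate edge %s->%s (%s,%s)",
                        e.source, e.target, e.polarity.symbol, e.logic.value)
                continue
            seen[e.key()] = e
            self.edges.append(e)
            for nid in (e.source, e.target):
                if nid not in self.nodes:
                    if strict_nodes:
                        undeclared.append(nid)
                    else:
                        self.nodes[nid] = NodeRecord(id=nid)
        if undeclared:
            raise ValidationError(
                "edges reference undeclared nodes: "
                + ", ".join(sorted(set(undeclared))))

    # -- queries ---------------------------------------------------------

    def node_ids(self) -> list[str]:
        return list(self.nodes)

    def in_edges(self, node: str) -> list[EdgeRecord]:
        return [e for e in self.edges if e.target == node]

    def out_edges(self, node: str) -> list[EdgeRecord]:
        return [e for e in self.edges if e.source == node]

    def in_degree(self, node: str) -> int:
        return sum(1 for e in self.edges if e.target == node)

    def out_degree(self, node: str) -> int:
        return sum(1 for e in self.edges if e.source == node)

    def to_multidigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for nid in sorted(self.nodes):
            rec = self.nodes[nid]
            g.add_node(nid, name=rec.name, entity_class=rec.entity_class)
        for e in sorted(self.edges, key=lambda e: (e.source, e.target, e.polarity.value)):
            g.add_edge(e.source, e.target,
                       polarity=e.polarity, logic=e.logic,
                       negative=e.is_negative)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_multidigraph())

    # -- validation / normalization -------------------------------------

    def validate(self, *, require_edges: bool = True) -> None:
        if require_edges and not self.edges:
            raise ValidationError("network has no edges")
        missing = sorted(
            {n for e in self.edges for n in (e.source, e.target)}
            - set(self.nodes))
        if missing:
            raise ValidationError(
                "edges reference undeclared nodes: " + ", ".join(missing))

    def fan_in_logic(self, node: str) -> Logic | None:
        """Single logic class of a node's incoming edges, or raise on a mix."""
        logics = {e.logic for e in self.in_edges(node)}
        if not logics:
            return None
        if len(logics) > 1:
            raise ValidationError(
                f"node {node!r} has mixed AND/OR fan-in; normalize first")
        return logics.pop()

    def is_normalized(self) -> bool:
        return all(
            len({e.logic for e in self.in_edges(n)}) <= 1 for n in self.nodes)

    def normalized(self) -> "LogicNetwork":
        """Return an equivalent network where every fan-in has a single
        logic class, inserting auxiliary grouping nodes where needed."""
        if self.is_normalized():
            return self
        nodes = dict(self.nodes)
        edges: list[EdgeRecord] = []
        by_target: dict[str, list[EdgeRecord]] = {}
        for e in self.edges:
            by_target.setdefault(e.target, []).append(e)
        handled: set[int] = set()
        for target, incoming in by_target.items():
            logics = {e.logic for e in incoming}
            if len(logics) <= 1:
                continue
            for logic in (Logic.AND, Logic.OR):
                group = [e for e in incoming if e.logic is logic]
                aux_id = f"{target}__{logic.value.lower()}_in"
                if aux_id in nodes:
                    raise ValidationError(
                        f"auxiliary id {aux_id!r} collides with existing node")
                nodes[aux_id] = NodeRecord(
                    id=aux_id, name=aux_id,
                    entity_class=EntityClass.AUXILIARY)
                for e in group:
                    handled.add(id(e))
                    edges.append(replace(e, target=aux_id))
                # the two grouped contributions combine multiplicatively
                edges.append(EdgeRecord(aux_id, target,
                                        Polarity.POSITIVE, Logic.AND))
        edges.extend(e for e in self.edges if id(e) not in handled)
        logger.info("normalized mixed fan-in by inserting auxiliary nodes")
        return LogicNetwork(nodes.values(), edges)

    # -- dunder ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def edge_multiset(self) -> frozenset[tuple[str, str, str, str]]:
        return frozenset(
            (e.source, e.target, e.polarity.symbol, e.logic.value)
            for e in self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogicNetwork):
            return NotImplemented
        return (set(self.nodes) == set(other.nodes)
                and self.edge_multiset() == other.edge_multiset())

    def __repr__(self) -> str:  # pragma: no cover
        return (f"LogicNetwork(nodes={len(self.nodes)}, "
                f"edges={len(self.edges)})")


# ---------------------------------------------------------------------------
# I/O: canonical tab-separated logic tables
# ---------------------------------------------------------------------------

_EDGE_HEADER = ("source_id", "target_id", "polarity", "logic")
_NODE_HEADER = ("id", "name", "entity_class")

_SOURCE_ALIASES = {"source_id", "source", "from", "src", "input"}
_TARGET_ALIASES = {"target_id", "target", "to", "dst", "output"}
_POLARITY_ALIASES = {"polarity", "sign", "effect", "pos_neg"}
_LOGIC_ALIASES = {"logic", "gate", "and_or"}

_POLARITY_VALUES = {
    "+": Polarity.POSITIVE, "positive": Polarity.POSITIVE,
    "activation": Polarity.POSITIVE, "activate": Polarity.POSITIVE,
    "1": Polarity.POSITIVE,
    "-": Polarity.NEGATIVE, "negative": Polarity.NEGATIVE,
    "inhibition": Polarity.NEGATIVE, "inhibit": Polarity.NEGATIVE,
    "-1": Polarity.NEGATIVE,
}


def _resolve_columns(header: Sequence[str]) -> dict[str, int]:
    cols = [c.strip().lower() for c in header]
    mapping: dict[str, int] = {}
    for role, aliases in (("source", _SOURCE_ALIASES),
                          ("target", _TARGET_ALIASES),
                          ("polarity", _POLARITY_ALIASES),
                          ("logic", _LOGIC_ALIASES)):
        for i, c in enumerate(cols):
            if c in aliases and role not in mapping:
                mapping[role] = i
        if role not in mapping:
            raise FormatError(
                f"missing required column for {role!r}; header was {header}")
    return mapping


def _parse_edge_row(fields: Sequence[str], cols: Mapping[str, int],
                    lineno: int) -> EdgeRecord:
    try:
        source = fields[cols["source"]].strip()
        target = fields[cols["target"]].strip()
        pol_raw = fields[cols["polarity"]].strip().lower()
        logic_raw = fields[cols["logic"]].strip().upper()
    except IndexError as exc:
        raise FormatError(f"line {lineno}: too few fields") from exc
    if pol_raw not in _POLARITY_VALUES:
        raise FormatError(f"line {lineno}: unknown polarity {pol_raw!r}")
    try:
        logic = Logic(logic_raw)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: unknown logic {logic_raw!r}") from exc
    return EdgeRecord(source, target, _POLARITY_VALUES[pol_raw], logic)


def _parse_node_row(fields: Sequence[str], lineno: int) -> NodeRecord:
    if len(fields) < 1 or not fields[0].strip():
        raise FormatError(f"line {lineno}: node row without id")
    nid = fields[0].strip()
    name = fields[1].strip() if len(fields) > 1 and fields[1].strip() else nid
    cls_raw = fields[2].strip().lower() if len(fields) > 2 else ""
    if not cls_raw:
        cls = EntityClass.AUXILIARY
    else:
        try:
            cls = EntityClass(cls_raw)
        except ValueError:
            logger.warning("line %d: unknown entity class %r mapped to "
                           "'auxiliary'", lineno, cls_raw)
            cls = EntityClass.AUXILIARY
    return NodeRecord(nid, name, cls)


def read_logic_table(path: str | Path | io.TextIOBase) -> LogicNetwork:
    """Read a logic network from a tab-separated table.

    The canonical layout has an optional ``# nodes`` section
    (``id<TAB>name<TAB>entity_class``) followed by an ``# edges`` section
    (``source_id<TAB>target_id<TAB>polarity<TAB>logic``).  A file without
    section markers is treated as a bare edge table; header column names are
    matched permissively (``source``/``from``/``src`` etc.).  Lines starting
    with ``#`` that are not section markers are comments.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        origin = "<stream>"
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        lines = p.read_text(encoding="utf-8").splitlines()
        origin = str(p)

    node_rows: list[tuple[int, list[str]]] = []
    edge_rows: list[tuple[int, list[str]]] = []
    section = "edges"
    has_markers = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            marker = stripped.lstrip("#").strip().lower()
            if marker == "nodes":
                section, has_markers = "nodes", True
            elif marker == "edges":
                section, has_markers = "edges", True
            continue
        fields = line.split("\t")
        if section == "nodes":
            node_rows.append((lineno, fields))
        else:
            edge_rows.append((lineno, fields))

    if not edge_rows:
        raise ValidationError(f"{origin}: no edges found")

    # first edge row must be the header
    header_lineno, header = edge_rows[0]
    cols = _resolve_columns(header)
    edges = [_parse_edge_row(f, cols, ln) for ln, f in edge_rows[1:]]
    if not edges:
        raise ValidationError(f"{origin}: edge section has a header but no rows")

    nodes: list[NodeRecord] = []
    if node_rows:
        start = 0
        first = [c.strip().lower() for c in node_rows[0][1]]
        if first and first[0] in {"id", "node_id"}:
            start = 1
        nodes = [_parse_node_row(f, ln) for ln, f in node_rows[start:]]

    net = LogicNetwork(nodes, edges, strict_nodes=bool(nodes) and has_markers)
    net.validate()
    return net


def write_logic_table(net: LogicNetwork, path: str | Path | io.TextIOBase) -> None:
    """Serialize *net* to the canonical sectioned logic-table format.

    Re-reading the written file reproduces a network with identical node ids
    and an identical edge multiset.  Refuses to serialize an empty network.
    """
    if not net.nodes:
        raise ValidationError("refusing to serialize an empty network")
    net.validate(require_edges=True)
    buf = io.StringIO()
    buf.write("# nodes\n")
    buf.write("\t".join(_NODE_HEADER) + "\n")
    for nid in sorted(net.nodes):
        rec = net.nodes[nid]
        buf.write(f"{rec.id}\t{rec.name}\t{rec.entity_class.value}\n")
    buf.write("# edges\n")
    buf.write("\t".join(_EDGE_HEADER) + "\n")
    for e in sorted(net.edges,
                    key=lambda e: (e.source, e.target, e.polarity.value)):
        buf.write(f"{e.source}\t{e.target}\t{e.polarity.symbol}"
                  f"\t{e.logic.value}\n")
    text = buf.getvalue()
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# Roles and test-case enumeration
# ---------------------------------------------------------------------------

def infer_roles(net: LogicNetwork,
                key_outputs: Iterable[str] | None = None) -> list[NodeRole]:
    """Flag root inputs (in-degree 0) and terminal outputs (out-degree 0).

    Key outputs default to the terminal outputs; pass *key_outputs* to
    designate other (possibly internal) readout nodes instead.
    """
    in_deg = {n: 0 for n in net.nodes}
    out_deg = {n: 0 for n in net.nodes}
    for e in net.edges:
        out_deg[e.source] += 1
        in_deg[e.target] += 1
    kos = set(key_outputs) if key_outputs is not None else None
    roles = []
    for nid in net.nodes:
        terminal = out_deg[nid] == 0
        roles.append(NodeRole(
            node_id=nid,
            is_root_input=in_deg[nid] == 0,
            is_terminal_output=terminal,
            is_key_output=(nid in kos) if kos is not None else terminal,
        ))
    return roles


def enumerate_test_cases(net: LogicNetwork,
                         roots: Iterable[str],
                         key_outputs: Iterable[str],
                         pathway: str | None = None) -> list[TestCase]:
    """Enumerate |roots| x |key_outputs| x 2 bidirectional test cases."""
    roots = list(dict.fromkeys(roots))
    kos = list(dict.fromkeys(key_outputs))
    unknown = [n for n in roots + kos if n not in net.nodes]
    if unknown:
        raise ValidationError(
            "roots/key outputs not in network: " + ", ".join(sorted(set(unknown))))
    overlap = sorted(set(roots) & set(kos))
    if overlap:
        raise ValidationError(
            "nodes listed as both root input and key output: "
            + ", ".join(overlap))
    cases = []
    for r in roots:
        for k in kos:
            for d in (Direction.UP, Direction.DOWN):
                cases.append(TestCase(root_input=r, direction=d,
                                      key_output=k, pathway=pathway))
    return cases
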