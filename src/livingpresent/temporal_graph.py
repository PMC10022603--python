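"""Temporal Bayesian-network scaffolding for models of time-consciousness.

Three temporal orders are constructed as directed acyclic graphs:

* **sequential** -- objective time as a causal chain, each moment depending
  only on its predecessor;
* **interpenetrated** -- subjective temporality, where the present moment is
  a collider receiving messages from both the just-past (retention) and the
  about-to-occur (protention);
* **integrated continuity** -- a two-coordinate lattice combining both: each
  node carries an objective step ``t`` and a subjective offset ``tau``
  relative to a reference event, develops bidirectionally at each event and
  advances unidirectionally across events.

The module also extracts Markov blankets of designated "present" nodes and
verifies conditional-independence structure with a brute-force d-separation
oracle (exhaustive path enumeration, chosen for oracle clarity over speed:
the lattices built here have at most tens of nodes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import networkx as nx

__all__ = [
    "TemporalOrder",
    "NodeRole",
    "TimeIndex",
    "TemporalNode",
    "TemporalDAG",
    "MarkovBlanket",
    "AsynchronyRecord",
    "build_temporal_dag",
    "markov_blanket",
    "is_d_separated",
    "blanket_asynchrony",
]


class TemporalOrder(str, Enum):
    SEQUENTIAL = "sequential"
    INTERPENETRATED = "interpenetrated"
    INTEGRATED = "integrated"


class NodeRole(str, Enum):
    HIDDEN = "hidden"
    OBSERVATION = "observation"


@dataclass(frozen=True, order=True)
class TimeIndex:
    """A coordinate pair: objective step ``t`` and subjective offset ``tau``.

    ``objective`` counts discrete world-time steps; ``subjective`` is an
    offset relative to a declared reference event (negative = retention side,
    positive = protention side).  Both are plain finite integers.
    """

    objective: int
    subjective: int

    def shifted(self, d_objective: int = 0, d_subjective: int = 0) -> "TimeIndex":
        return TimeIndex(self.objective + d_objective, self.subjective + d_subjective)


@dataclass(frozen=True)
class TemporalNode:
    """A node of a temporal DAG: a (t, tau) coordinate plus a role.

    Identity (equality/hash) is the (index, role) pair; the free-text label
    is descriptive only, so relabelling never changes graph membership.
    """

    index: TimeIndex
    role: NodeRole = NodeRole.HIDDEN
    label: str = field(default="", compare=False)

    @property
    def is_hidden(self) -> bool:
        return self.role is NodeRole.HIDDEN

    def node_id(self) -> str:
        return f"{self.role.value[0]}:{self.index.objective}:{self.index.subjective}"


@dataclass
class TemporalDAG:
    """A directed acyclic graph over :class:`TemporalNode` objects.

    Edges point in the direction of conditional dependency (parent -> child).
    ``reference`` designates the present-moment node all subjective offsets
    are read against.
    """

    graph: nx.DiGraph
    order: TemporalOrder
    reference: TemporalNode

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("temporal graph must be acyclic")

    @property
    def nodes(self) -> set[TemporalNode]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[TemporalNode, TemporalNode]]:
        return list(self.graph.edges)

    def require(self, node: TemporalNode) -> TemporalNode:
        if node not in self.graph:
            raise KeyError(f"node {node.node_id()} is not in the graph")
        # return the stored instance so callers see the canonical label
        for stored in self.graph.nodes:
            if stored == node:
                return stored
        raise KeyError(f"node {node.node_id()} is not in the graph")

    def parents(self, node: TemporalNode) -> set[TemporalNode]:
        self.require(node)
        return set(self.graph.predecessors(node))

    def children(self, node: TemporalNode) -> set[TemporalNode]:
        self.require(node)
        return set(self.graph.successors(node))

    def find(self, objective: int, subjective: int,
             role: NodeRole = NodeRole.HIDDEN) -> TemporalNode:
        return self.require(TemporalNode(TimeIndex(objective, subjective), role))

    # ------------------------------------------------------------------ io
    def to_dot(self) -> str:
        """Render the graph as Graphviz DOT text."""
        lines = ["digraph temporal {", "  rankdir=LR;"]
        for node in sorted(self.graph.nodes,
                           key=lambda n: (n.index, n.role.value)):
            shape = "ellipse" if node.is_hidden else "box"
            label = (f"({node.index.objective},{node.index.subjective}) "
                     f"{node.role.value}\\n{node.label}")
            lines.append(f'  "{node.node_id()}" [shape={shape}, label="{label}"];')
        for parent, child in sorted(
                self.graph.edges,
                key=lambda e: (e[0].index, e[0].role.value, e[1].index)):
            lines.append(f'  "{parent.node_id()}" -> "{child.node_id()}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            "order": self.order.value,
            "reference": self.reference.node_id(),
            "nodes": [
                {
                    "id": n.node_id(),
                    "objective": n.index.objective,
                    "subjective": n.index.subjective,
                    "role": n.role.value,
                    "label": n.label,
                }
                for n in sorted(self.graph.nodes,
                                key=lambda n: (n.index, n.role.value))
            ],
            "edges": [
                [p.node_id(), c.node_id()]
                for p, c in sorted(
                    self.graph.edges,
                    key=lambda e: (e[0].index, e[0].role.value, e[1].index))
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TemporalDAG":
        payload = json.loads(text)
        nodes: dict[str, TemporalNode] = {}
        for entry in payload["nodes"]:
            node = TemporalNode(
                TimeIndex(int(entry["objective"]), int(entry["subjective"])),
                NodeRole(entry["role"]),
                entry.get("label", ""),
            )
            nodes[entry["id"]] = node
        graph = nx.DiGraph()
        graph.add_nodes_from(nodes.values())
        for parent_id, child_id in payload["edges"]:
            graph.add_edge(nodes[parent_id], nodes[child_id])
        return cls(graph, TemporalOrder(payload["order"]),
                   nodes[payload["reference"]])


@dataclass(frozen=True)
class MarkovBlanket:
    """The node set statistically bounding a target: parents, children and
    co-parents of children."""

    target: TemporalNode
    members: frozenset[TemporalNode]

    def __post_init__(self) -> None:
        if self.target in self.members:
            raise ValueError("target cannot be a member of its own blanket")


@dataclass(frozen=True)
class AsynchronyRecord:
    """Summary of the temporal spread of a blanket around its target."""

    objective_span: int
    past_count: int
    future_count: int
    imbalanced: bool


# --------------------------------------------------------------------------
# constructors
# --------------------------------------------------------------------------

def _relative_label(index: TimeIndex, reference: TimeIndex) -> str:
    key = (index.objective, index.subjective)
    ref = (reference.objective, reference.subjective)
    if key == ref:
        return "primal impression"
    return "retention" if key < ref else "protention"


def build_temporal_dag(order: TemporalOrder | str,
                       objective_horizon: int,
                       subjective_depth: int) -> TemporalDAG:
    """Construct one of the three temporal-order DAGs.

    Parameters
    ----------
    order
        ``sequential``, ``interpenetrated`` or ``integrated``.
    objective_horizon
        Number of objective time steps (>= 2).
    subjective_depth
        Retention/protention depth (>= 1).  Controls the subjective extent of
        the integrated lattice; the sequential and interpenetrated orders are
        one-dimensional and ignore it beyond validation.
    """
    order = TemporalOrder(order)
    if objective_horizon < 2:
        raise ValueError(f"objective_horizon must be >= 2, got {objective_horizon}")
    if subjective_depth < 1:
        raise ValueError(f"subjective_depth must be >= 1, got {subjective_depth}")

    if order is TemporalOrder.SEQUENTIAL:
        return _build_sequential(objective_horizon)
    if order is TemporalOrder.INTERPENETRATED:
        return _build_interpenetrated(objective_horizon)
    return _build_integrated(objective_horizon, subjective_depth)


def _build_sequential(horizon: int) -> TemporalDAG:
    # A causal chain in objective time: each moment depends on its predecessor.
    ref_index = TimeIndex(horizon // 2, 0)
    nodes = [
        TemporalNode(TimeIndex(t, 0), NodeRole.HIDDEN,
                     _relative_label(TimeIndex(t, 0), ref_index))
        for t in range(horizon)
    ]
    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    for left, right in zip(nodes, nodes[1:]):
        graph.add_edge(left, right)
    return TemporalDAG(graph, TemporalOrder.SEQUENTIAL, nodes[horizon // 2])


def _build_interpenetrated(horizon: int) -> TemporalDAG:
    # Subjective temporality: retention and protention both point into the
    # present, which is therefore a collider.  Offsets are centred on zero.
    offsets = [tau - horizon // 2 for tau in range(horizon)]
    ref_index = TimeIndex(0, 0)
    nodes = {
        tau: TemporalNode(TimeIndex(0, tau), NodeRole.HIDDEN,
                          _relative_label(TimeIndex(0, tau), ref_index))
        for tau in offsets
    }
    graph = nx.DiGraph()
    graph.add_nodes_from(nodes.values())
    for tau in offsets:
        if tau < 0 and tau + 1 in nodes:
            graph.add_edge(nodes[tau], nodes[tau + 1])
        elif tau > 0 and tau - 1 in nodes:
            graph.add_edge(nodes[tau], nodes[tau - 1])
    return TemporalDAG(graph, TemporalOrder.INTERPENETRATED, nodes[0])


def _build_integrated(horizon: int, depth: int) -> TemporalDAG:
    """Integrated continuity: hidden nodes at subjective offsets 0..depth,
    observed retention nodes at offsets -depth..-1, replicated at every
    objective step.

    Every hidden node (t, tau) takes whichever of the homogeneous parent set
    exists on the finite lattice: hidden (t-1, tau+1), hidden (t, tau+1) and
    observed (t, tau-1).  Nodes missing parents because the lattice is
    truncated are boundary nodes.
    """
    ref_index = TimeIndex(horizon // 2, 0)
    hidden: dict[tuple[int, int], TemporalNode] = {}
    observed: dict[tuple[int, int], TemporalNode] = {}
    for t in range(horizon):
        for tau in range(depth + 1):
            idx = TimeIndex(t, tau)
            hidden[(t, tau)] = TemporalNode(idx, NodeRole.HIDDEN,
                                            _relative_label(idx, ref_index))
        for tau in range(-depth, 0):
            idx = TimeIndex(t, tau)
            observed[(t, tau)] = TemporalNode(idx, NodeRole.OBSERVATION,
                                              "retention")
    graph = nx.DiGraph()
    graph.add_nodes_from(hidden.values())
    graph.add_nodes_from(observed.values())
    for (t, tau), node in hidden.items():
        if (t - 1, tau + 1) in hidden:
            graph.add_edge(hidden[(t - 1, tau + 1)], node)
        if (t, tau + 1) in hidden:
            graph.add_edge(hidden[(t, tau + 1)], node)
        if (t, tau - 1) in observed:
            graph.add_edge(observed[(t, tau - 1)], node)
    return TemporalDAG(graph, TemporalOrder.INTEGRATED,
                       hidden[(horizon // 2, 0)])


# --------------------------------------------------------------------------
# blankets and d-separation
# --------------------------------------------------------------------------

def markov_blanket(dag: TemporalDAG, target: TemporalNode) -> MarkovBlanket:
    """Parents, children and co-parents of children of ``target``.

    Conditioning on the returned members renders the target d-separated from
    every other node of the graph (verified exhaustively in the test suite
    with :func:`is_d_separated`).
    """
    target = dag.require(target)
    members: set[TemporalNode] = set()
    members |= dag.parents(target)
    children = dag.children(target)
    members |= children
    for child in children:
        members |= dag.parents(child)
    members.discard(target)
    return MarkovBlanket(target, frozenset(members))


def is_d_separated(dag: TemporalDAG,
                   x: TemporalNode,
                   y: TemporalNode,
                   conditioning: Iterable[TemporalNode] = ()) -> bool:
    """Brute-force d-separation by exhaustive undirected path enumeration.

    A path is blocked if some chain/fork node on it is conditioned, or some
    collider on it has neither itself nor any descendant conditioned.  The
    nodes are d-separated iff every path is blocked.
    """
    x = dag.require(x)
    y = dag.require(y)
    conditioning = {dag.require(z) for z in conditioning}
    if x == y:
        raise ValueError("x and y must be distinct nodes")
    if x in conditioning or y in conditioning:
        raise ValueError("x and y must not appear in the conditioning set")

    graph = dag.graph
    undirected = graph.to_undirected(as_view=True)
    # collider unblocking: the collider or any of its descendants conditioned
    opens_collider = {
        node: (node in conditioning
               or bool(nx.descendants(graph, node) & conditioning))
        for node in graph.nodes
    }
    for path in nx.all_simple_paths(undirected, x, y):
        active = True
        for prev, mid, nxt in zip(path, path[1:], path[2:]):
            collider = graph.has_edge(prev, mid) and graph.has_edge(nxt, mid)
            if collider:
                if not opens_collider[mid]:
                    active = False
                    break
            elif mid in conditioning:
                active = False
                break
        if active:
            return False
    return True


def blanket_asynchrony(blanket: MarkovBlanket) -> AsynchronyRecord:
    """Temporal spread of a blanket: objective span and past/future balance.

    Members are classified as past or future of the target by objective step,
    with subjective offset breaking ties (a retention node at the target's own
    objective step counts as past).  An imbalance between the two sides is
    the structural signature of continuity: the present keeps more of one
    temporal direction than the other.
    """
    if not blanket.members:
        raise ValueError("blanket is empty")
    t_ref = (blanket.target.index.objective, blanket.target.index.subjective)
    objectives = [m.index.objective for m in blanket.members]
    past = sum(
        1 for m in blanket.members
        if (m.index.objective, m.index.subjective) < t_ref
    )
    future = len(blanket.members) - past
    return AsynchronyRecord(
        objective_span=max(objectives) - min(objectives),
        past_count=past,
        future_count=future,
        imbalanced=past != future,
    )
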