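"""Directed dependency graphs over named states and Markov-blanket partitions.

A dependency graph records "who influences whose flow": an edge ``u -> v``
means the time derivative of state ``v`` depends on the current value of
state ``u``.  Self-dependence is universal (every flow depends on its own
state) and is therefore *implicit*: self-loops are never stored, and
:func:`unroll_one_step` reinstates them as ``x_t -> x_{t+1}`` edges when a
directed acyclic view is needed.

The blanket machinery follows the standard four-way partition of states into
internal (mu), sensory (s), active (a) and external (eta) sets.  A partition
is admissible when the flow of internal and external states never depends
directly on one another: the four forbidden dependency classes are
``mu->s``, ``mu->eta``, ``eta->a`` and ``eta->mu``.
"""

from __future__ import annotations

import enum
import itertools
from collections import deque
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "ROLES",
    "StateNode",
    "DependencyGraph",
    "BlanketPartition",
    "ViolationRule",
    "Violation",
    "GraphError",
    "PartitionError",
    "CyclicGraphError",
    "pearl_blanket",
    "classify_blanket",
    "validate_partition",
    "d_separated",
    "unroll_one_step",
    "partition_from_roles",
]

ROLES = ("internal", "sensory", "active", "external", "unassigned")


class GraphError(ValueError):
    """Malformed graph input (unknown node, duplicate id, ...)."""


class PartitionError(GraphError):
    """State sets passed to a blanket operation do not form a partition."""


class CyclicGraphError(GraphError):
    """An operation requiring a DAG was handed a cyclic graph."""


@dataclass(frozen=True)
class StateNode:
    """A named state at some spatial scale.

    Parameters
    ----------
    id
        Unique label within a graph.
    role
        One of ``internal``, ``sensory``, ``active``, ``external`` or
        ``unassigned``.
    scale
        Non-negative coarse-graining level; 0 is the finest scale.
    group
        Optional macro-unit label used by coarse-graining.
    """

    id: str
    role: str = "unassigned"
    scale: int = 0
    group: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise GraphError(
                f"role {self.role!r} of node {self.id!r} is not one of {ROLES}"
            )
        if self.scale < 0:
            raise GraphError(f"node {self.id!r} has negative scale {self.scale}")


class DependencyGraph:
    """Directed graph over :class:`StateNode` objects, without self-loops.

    Edge signs (excitatory / inhibitory / unsigned) are carried as metadata
    and ignored by every blanket computation: blankets depend on dependency,
    not on its sign.
    """

    def __init__(
        self,
        nodes: Iterable[StateNode | str] = (),
        edges: Iterable[tuple[str, str]] = (),
        signs: Mapping[tuple[str, str], str] | None = None,
    ) -> None:
        self._nodes: dict[str, StateNode] = {}
        self._parents: dict[str, set[str]] = {}
        self._children: dict[str, set[str]] = {}
        self.signs: dict[tuple[str, str], str] = {}
        for node in nodes:
            self.add_node(node)
        for u, v in edges:
            self.add_edge(u, v, sign=(signs or {}).get((u, v), "unsigned"))

    # -- construction -----------------------------------------------------
    def add_node(self, node: StateNode | str, **attrs) -> StateNode:
        if isinstance(node, str):
            node = StateNode(node, **attrs)
        if node.id in self._nodes:
            raise GraphError(f"duplicate node id {node.id!r}")
        self._nodes[node.id] = node
        self._parents[node.id] = set()
        self._children[node.id] = set()
        return node

    def add_edge(self, u: str, v: str, sign: str = "unsigned") -> None:
        for endpoint in (u, v):
            if endpoint not in self._nodes:
                raise GraphError(f"edge ({u!r}, {v!r}) references unknown node {endpoint!r}")
        if u == v:
            raise GraphError(
                f"self-loop on {u!r}: self-dependence is implicit and never stored"
            )
        if sign not in ("excitatory", "inhibitory", "unsigned"):
            raise GraphError(f"unknown edge sign {sign!r}")
        self._children[u].add(v)
        self._parents[v].add(u)
        self.signs[(u, v)] = sign

    def remove_edge(self, u: str, v: str) -> None:
        self._children[u].discard(v)
        self._parents[v].discard(u)
        self.signs.pop((u, v), None)

    def set_role(self, node_id: str, role: str) -> None:
        self._nodes[node_id] = replace(self._nodes[node_id], role=role)

    # -- queries ----------------------------------------------------------
    @property
    def node_ids(self) -> set[str]:
        return set(self._nodes)

    @property
    def nodes(self) -> dict[str, StateNode]:
        return dict(self._nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(u, v) for u, kids in self._children.items() for v in kids}

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._children.get(u, ())

    def parents(self, node_id: str) -> set[str]:
        self._require(node_id)
        return set(self._parents[node_id])

    def children(self, node_id: str) -> set[str]:
        self._require(node_id)
        return set(self._children[node_id])

    def parents_of(self, ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for i in ids:
            out |= self.parents(i)
        return out

    def children_of(self, ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for i in ids:
            out |= self.children(i)
        return out

    def roles(self) -> dict[str, str]:
        return {i: n.role for i, n in self._nodes.items()}

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def _require(self, node_id: str) -> None:
        if node_id not in self._nodes:
            raise GraphError(f"unknown node id {node_id!r}")

    # -- conversion -------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self._nodes.values():
            attrs = {"role": node.role, "scale": node.scale}
            if node.group is not None:
                attrs["group"] = node.group
            g.add_node(node.id, **attrs)
        for u, v in self.edges:
            g.add_edge(u, v, sign=self.signs.get((u, v), "unsigned"))
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DependencyGraph":
        out = cls()
        for node_id, data in g.nodes(data=True):
            out.add_node(
                StateNode(
                    str(node_id),
                    role=data.get("role", "unassigned"),
                    scale=int(data.get("scale", 0)),
                    group=data.get("group"),
                )
            )
        for u, v, data in g.edges(data=True):
            if u == v:
                continue
            out.add_edge(str(u), str(v), sign=data.get("sign", "unsigned"))
        return out

    def copy(self) -> "DependencyGraph":
        out = DependencyGraph()
        out._nodes = dict(self._nodes)
        out._parents = {k: set(v) for k, v in self._parents.items()}
        out._children = {k: set(v) for k, v in self._children.items()}
        out.signs = dict(self.signs)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, DependencyGraph):
            return NotImplemented
        return self.node_ids == other.node_ids and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover
        return f"DependencyGraph({len(self._nodes)} nodes, {len(self.edges)} edges)"


@dataclass(frozen=True)
class BlanketPartition:
    """Four-way role assignment: internal (mu), sensory, active, external (eta)."""

    internal: frozenset[str]
    sensory: frozenset[str]
    active: frozenset[str]
    external: frozenset[str]

    def __init__(self, internal, sensory, active, external):
        object.__setattr__(self, "internal", frozenset(internal))
        object.__setattr__(self, "sensory", frozenset(sensory))
        object.__setattr__(self, "active", frozenset(active))
        object.__setattr__(self, "external", frozenset(external))
        sets = [self.internal, self.sensory, self.active, self.external]
        total = sum(len(s) for s in sets)
        union = frozenset().union(*sets)
        if total != len(union):
            raise PartitionError("partition sets are not disjoint")

    @property
    def blanket(self) -> frozenset[str]:
        return self.sensory | self.active

    @property
    def all_ids(self) -> frozenset[str]:
        return self.internal | self.sensory | self.active | self.external

    def roles(self) -> dict[str, str]:
        out = {}
        for role in ("internal", "sensory", "active", "external"):
            for i in getattr(self, role):
                out[i] = role
        return out

    def swapped(self) -> "BlanketPartition":
        """The reversed perspective: internal<->external, sensory<->active."""
        return BlanketPartition(
            internal=self.external,
            sensory=self.active,
            active=self.sensory,
            external=self.internal,
        )

    def to_dict(self) -> dict[str, list[str]]:
        return {
            role: sorted(getattr(self, role))
            for role in ("internal", "sensory", "active", "external")
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "BlanketPartition":
        return cls(
            internal=d.get("internal", ()),
            sensory=d.get("sensory", ()),
            active=d.get("active", ()),
            external=d.get("external", ()),
        )


class ViolationRule(str, enum.Enum):
    """The four dependency classes a blanket partition forbids."""

    MU_TO_S = "mu->s"
    MU_TO_ETA = "mu->eta"
    ETA_TO_A = "eta->a"
    ETA_TO_MU = "eta->mu"


_FORBIDDEN: dict[tuple[str, str], ViolationRule] = {
    ("internal", "sensory"): ViolationRule.MU_TO_S,
    ("internal", "external"): ViolationRule.MU_TO_ETA,
    ("external", "active"): ViolationRule.ETA_TO_A,
    ("external", "internal"): ViolationRule.ETA_TO_MU,
}


@dataclass(frozen=True)
class Violation:
    """A single edge that breaks one of the four forbidden dependency classes."""

    edge: tuple[str, str]
    rule: ViolationRule

    def to_dict(self) -> dict:
        return {"edge": list(self.edge), "rule": self.rule.value}


def partition_from_roles(graph: DependencyGraph) -> BlanketPartition:
    """Build a partition from the roles stored on the graph's nodes.

    Raises if any node is still ``unassigned``.
    """
    roles = graph.roles()
    unassigned = sorted(i for i, r in roles.items() if r == "unassigned")
    if unassigned:
        raise PartitionError(f"nodes without a role: {unassigned}")
    return BlanketPartition(
        internal={i for i, r in roles.items() if r == "internal"},
        sensory={i for i, r in roles.items() if r == "sensory"},
        active={i for i, r in roles.items() if r == "active"},
        external={i for i, r in roles.items() if r == "external"},
    )


def pearl_blanket(graph: DependencyGraph, targets: Iterable[str]) -> set[str]:
    """Markov blanket of ``targets``: parents, children and co-parents.

    Returns ``(pa(T) | ch(T) | pa(ch(T))) \\ T``.  Deterministic; does not
    mutate the graph.
    """
    targets = set(targets)
    for t in targets:
        if t not in graph:
            raise GraphError(f"unknown target id {t!r}")
    children = graph.children_of(targets)
    blanket = graph.parents_of(targets) | children | graph.parents_of(children)
    return blanket - targets


def classify_blanket(
    graph: DependencyGraph,
    internal: Iterable[str],
    external: Iterable[str],
    blanket: Iterable[str],
) -> tuple[set[str], set[str], set[str], list[Violation]]:
    """Split a blanket into sensory / active / ambiguous sets.

    A blanket node whose parents include internal states (and no external
    ones) mediates inside->outside influence and is *active*; one with
    external parents only is *sensory*; one with parents in both cannot
    satisfy the flow constraints under any assignment and is reported as a
    violation (one per offending edge); one with parents in neither is
    *ambiguous* and left to the caller (a downstream pipeline may force
    ambiguous nodes to sensory).
    """
    internal, external, blanket = set(internal), set(external), set(blanket)
    if internal & external or internal & blanket or external & blanket:
        raise PartitionError("internal, external and blanket sets must be disjoint")
    expected = graph.node_ids - internal - external
    if blanket != expected:
        raise PartitionError(
            "blanket must be the complement of internal and external; "
            f"missing {sorted(expected - blanket)}, extra {sorted(blanket - expected)}"
        )
    sensory: set[str] = set()
    active: set[str] = set()
    ambiguous: set[str] = set()
    violations: list[Violation] = []
    for b in sorted(blanket):
        pa = graph.parents(b)
        mu_pa = pa & internal
        eta_pa = pa & external
        if mu_pa and eta_pa:
            violations.extend(
                Violation((m, b), ViolationRule.MU_TO_S) for m in sorted(mu_pa)
            )
            violations.extend(
                Violation((e, b), ViolationRule.ETA_TO_A) for e in sorted(eta_pa)
            )
        elif mu_pa:
            active.add(b)
        elif eta_pa:
            sensory.add(b)
        else:
            ambiguous.add(b)
    return sensory, active, ambiguous, violations


def validate_partition(
    graph: DependencyGraph, partition: BlanketPartition
) -> list[Violation]:
    """Every edge that breaks the blanket flow constraints; empty iff valid.

    The forbidden classes are internal->sensory, internal->external,
    external->active and external->internal.  Removing edges can never
    create a violation (losses preserve the blanket; gains may destroy it).
    """
    if partition.all_ids != graph.node_ids:
        missing = sorted(graph.node_ids - partition.all_ids)
        extra = sorted(partition.all_ids - graph.node_ids)
        raise PartitionError(
            f"partition does not cover the graph; missing {missing}, extra {extra}"
        )
    role = partition.roles()
    out = [
        Violation((u, v), _FORBIDDEN[(role[u], role[v])])
        for u, v in sorted(graph.edges)
        if (role[u], role[v]) in _FORBIDDEN
    ]
    return out


def _check_disjoint_subsets(graph: DependencyGraph, *sets: set[str]) -> None:
    seen: set[str] = set()
    for s in sets:
        for i in s:
            if i not in graph:
                raise GraphError(f"unknown node id {i!r}")
            if i in seen:
                raise GraphError(f"node {i!r} appears in more than one query set")
        seen |= s


def d_separated(
    graph: DependencyGraph,
    A: Iterable[str],
    B: Iterable[str],
    C: Iterable[str],
) -> bool:
    """d-separation verdict for disjoint node sets on a DAG.

    Implemented by Bayes-ball reachability: returns True iff no active
    trail connects ``A`` and ``B`` given conditioning set ``C``.  Symmetric
    in ``A`` and ``B``.  Cyclic graphs are rejected; unroll them first with
    :func:`unroll_one_step`.
    """
    A, B, C = set(A), set(B), set(C)
    _check_disjoint_subsets(graph, A, B, C)
    if not graph.is_acyclic():
        raise CyclicGraphError(
            "d-separation is defined on DAGs; apply unroll_one_step to the "
            "cyclic flow graph first"
        )
    if not A or not B:
        return True

    # ancestors of C (inclusive), needed for collider activation
    anc_c: set[str] = set()
    stack = list(C)
    while stack:
        n = stack.pop()
        if n in anc_c:
            continue
        anc_c.add(n)
        stack.extend(graph.parents(n))

    # Bayes-ball: states are (node, direction); "up" = reached from a child,
    # "down" = reached from a parent.
    visited: set[tuple[str, str]] = set()
    queue: deque[tuple[str, str]] = deque((a, "up") for a in A)
    while queue:
        node, direction = queue.popleft()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node in B:
            return False
        if direction == "up":
            if node not in C:
                for p in graph.parents(node):
                    queue.append((p, "up"))
                for c in graph.children(node):
                    queue.append((c, "down"))
        else:  # reached along an edge from a parent
            if node not in C:
                for c in graph.children(node):
                    queue.append((c, "down"))
            if node in anc_c:
                for p in graph.parents(node):
                    queue.append((p, "up"))
    return True


def time_label(node_id: str, slice_index: int) -> str:
    """Label of a time-indexed copy of a node in an unrolled graph."""
    suffix = "t" if slice_index == 0 else f"t+{slice_index}"
    return f"{node_id}@{suffix}"


def unroll_one_step(graph: DependencyGraph) -> DependencyGraph:
    """Two-slice (dynamic Bayesian network) view of a cyclic flow graph.

    Each node ``x`` becomes ``x@t`` and ``x@t+1``; ``x@t+1`` has parents
    ``{y@t : y -> x}`` plus ``x@t`` (the implicit self-dependence).  The
    result is acyclic by construction, so d-separation applies.
    """
    out = DependencyGraph()
    for node in graph.nodes.values():
        for k in (0, 1):
            out.add_node(
                StateNode(time_label(node.id, k), role=node.role,
                          scale=node.scale, group=node.group)
            )
    for node_id in graph.node_ids:
        out.add_edge(time_label(node_id, 0), time_label(node_id, 1))
    for u, v in graph.edges:
        out.add_edge(time_label(u, 0), time_label(v, 1),
                     sign=graph.signs.get((u, v), "unsigned"))
    return out


def all_dags_in_order(n: int) -> Iterator[DependencyGraph]:
    """Every DAG on ``n`` nodes whose edges respect the order x0 < ... < x(n-1).

    Every labelled DAG is isomorphic to exactly one of these, and blanket
    computations commute with relabelling, so iterating them is exhaustive
    over DAG structures.
    """
    labels = [f"x{i}" for i in range(n)]
    pairs = [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)]
    for r in range(len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            yield DependencyGraph(nodes=labels, edges=combo)
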