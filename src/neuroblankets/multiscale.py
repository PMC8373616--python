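"""Coarse-graining of dependency graphs and recursive ("blankets of
blankets") analysis across spatial scales.

A coarse-graining maps micro nodes to macro units; the induced macro graph
has an edge A -> B exactly when some micro edge crosses from A into B.
Macro edges are existential, not weighted: blanket structure needs only the
presence of a dependency.  The soundness bridge :func:`macro_ci_check`
verifies that a partition declared valid at the macro scale really does
d-separate the corresponding micro states in the one-step unrolled graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .graph import (
    BlanketPartition,
    DependencyGraph,
    GraphError,
    StateNode,
    classify_blanket,
    d_separated,
    pearl_blanket,
    time_label,
    unroll_one_step,
    validate_partition,
)

__all__ = [
    "CoarseGraining",
    "coarse_grain",
    "compose_groupings",
    "nested_blankets",
    "macro_ci_check",
]


@dataclass(frozen=True)
class CoarseGraining:
    """Micro node id -> macro unit label, with a scale increment >= 1."""

    mapping: Mapping[str, str]
    scale_increment: int = 1

    def __post_init__(self) -> None:
        if self.scale_increment < 1:
            raise GraphError(
                f"scale increment must be >= 1, got {self.scale_increment}")
        for micro, macro in self.mapping.items():
            if not macro:
                raise GraphError(f"empty macro label for micro node {micro!r}")

    @classmethod
    def singleton(cls, graph: DependencyGraph) -> "CoarseGraining":
        """The identity grouping: every node its own macro unit."""
        return cls({i: i for i in graph.node_ids})


def coarse_grain(graph: DependencyGraph, grouping: CoarseGraining) -> DependencyGraph:
    """Quotient graph induced by a grouping.

    Macro node A gains an edge to macro node B iff some micro edge u -> v
    has u in A and v in B with A != B; within-group edges are dropped.
    Macro nodes sit ``scale_increment`` above the finest micro scale and
    start with role ``unassigned`` (roles are a per-scale choice, not
    inherited).
    """
    unmapped = sorted(graph.node_ids - set(grouping.mapping))
    if unmapped:
        raise GraphError(f"grouping does not cover micro nodes: {unmapped}")
    base_scale = max((n.scale for n in graph.nodes.values()), default=0)
    macro_scale = base_scale + grouping.scale_increment
    out = DependencyGraph()
    for macro in sorted(set(grouping.mapping[i] for i in graph.node_ids)):
        out.add_node(StateNode(macro, scale=macro_scale))
    for u, v in graph.edges:
        a, b = grouping.mapping[u], grouping.mapping[v]
        if a != b and not out.has_edge(a, b):
            out.add_edge(a, b)
    return out


def compose_groupings(
    first: CoarseGraining, second: CoarseGraining
) -> CoarseGraining:
    """The single grouping equivalent to applying ``first`` then ``second``."""
    return CoarseGraining(
        {micro: second.mapping[macro] for micro, macro in first.mapping.items()},
        scale_increment=first.scale_increment + second.scale_increment,
    )


def nested_blankets(
    graph: DependencyGraph,
    groupings: Sequence[CoarseGraining],
    internal_choices: Sequence[Iterable[str]],
    force_ambiguous: str = "sensory",
) -> list[dict]:
    """Recursive blanket ladder across scales.

    At each rung the graph is coarse-grained, the Markov blanket of the
    chosen internal set is extracted (parents, children, co-parents), the
    blanket is classified into sensory/active states, and the resulting
    partition is validated.  Ambiguous blanket nodes (no internal or
    external parents) are assigned to ``force_ambiguous`` so the rung
    yields a complete partition; the ambiguity is still reported.
    """
    if len(groupings) != len(internal_choices):
        raise GraphError(
            f"{len(groupings)} groupings but {len(internal_choices)} internal choices")
    if force_ambiguous not in ("sensory", "active"):
        raise GraphError(f"force_ambiguous must be sensory or active")
    ladder: list[dict] = []
    current = graph
    for grouping, internal in zip(groupings, internal_choices):
        current = coarse_grain(current, grouping)
        internal = set(internal)
        missing = sorted(internal - current.node_ids)
        if missing:
            raise GraphError(
                f"internal choice names unknown macro units: {missing}")
        blanket = pearl_blanket(current, internal)
        external = current.node_ids - internal - blanket
        sensory, active, ambiguous, cls_violations = classify_blanket(
            current, internal, external, blanket)
        if force_ambiguous == "sensory":
            sensory = sensory | ambiguous
        else:
            active = active | ambiguous
        partition = BlanketPartition(
            internal=internal, sensory=sensory, active=active, external=external)
        violations = validate_partition(current, partition)
        scale = max(n.scale for n in current.nodes.values())
        ladder.append({
            "scale": scale,
            "partition": partition,
            "classification": {
                "sensory": sorted(sensory),
                "active": sorted(active),
                "ambiguous": sorted(ambiguous),
                "violations": cls_violations,
            },
            "violations": violations,
        })
    return ladder


def macro_ci_check(
    micro_graph: DependencyGraph,
    grouping: CoarseGraining,
    macro_partition: BlanketPartition,
) -> bool:
    """Soundness bridge: does the macro partition d-separate micro states?

    Lifts the macro roles back to the micro nodes they contain and checks
    both one-step autonomy statements on the unrolled micro graph:

    * next-slice internal and active states are d-separated from the
      current-slice external states given the current internal and blanket
      states (external states influence neither flow), and
    * next-slice external and sensory states are d-separated from the
      current-slice internal states given the current external and blanket
      states (the mirror statement).

    Together these hold iff no micro edge crosses any of the four
    forbidden role pairs; a single internal-vs-external statement would
    miss a gained external->active (or internal->sensory) edge, whose
    victim is a blanket state rather than an internal one.
    """
    macro_graph = coarse_grain(micro_graph, grouping)
    if macro_partition.all_ids != macro_graph.node_ids:
        raise GraphError(
            "macro partition does not cover the coarse-grained graph")
    role_of_macro = macro_partition.roles()
    micro_role = {i: role_of_macro[grouping.mapping[i]] for i in micro_graph.node_ids}
    unrolled = unroll_one_step(micro_graph)

    def autonomy(near: tuple[str, str], far: str) -> bool:
        A = {time_label(i, 1) for i, r in micro_role.items() if r in near}
        B = {time_label(i, 0) for i, r in micro_role.items() if r == far}
        C = {time_label(i, 0) for i, r in micro_role.items() if r != far}
        return d_separated(unrolled, A, B, C)

    return (autonomy(("internal", "active"), "external")
            and autonomy(("external", "sensory"), "internal"))
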