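"""Dependency-graph tracing: attribute remote target sets to regulators.

A regulator's dependency graph is everything reachable downstream of it over
directed edges of any interaction type.  Its *remote targets* are the members
of that closure that were actually measured (intersection with the reference
universe).  Competitive regulation is handled by the exclusion rule: a target
at least as close (in unweighted steps) to a competing regulator as to the
regulator of interest is removed from the regulator's attributed set before
enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .network_model import (
    DifferentialSet,
    InteractionNetwork,
    InteractionType,
    ReferenceUniverse,
)

__all__ = [
    "TargetAttribution",
    "downstream_targets",
    "exclude_competitor",
    "candidate_competitors",
    "direct_targets",
]


@dataclass
class TargetAttribution:
    """Remote-target attribution for one regulator.

    ``distances`` holds the shortest downstream step count from the regulator
    to every member of ``full_targets``; ``per_competitor`` caches the reduced
    target set obtained by excluding each competitor considered so far.
    """

    regulator: str
    full_targets: frozenset[str]
    distances: dict[str, int]
    per_competitor: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.regulator in self.full_targets:
            raise ValueError("a regulator cannot be its own target")
        missing = self.full_targets - self.distances.keys()
        if missing:
            raise ValueError(f"distances missing for targets: {sorted(missing)[:5]}")


def _require_node(net: InteractionNetwork, node: str, role: str) -> None:
    if node not in net.nodes:
        raise KeyError(f"{role} {node!r} is not a node of the network")


def _bfs_distances(
    net: InteractionNetwork, source: str, max_depth: Optional[int] = None
) -> dict[str, int]:
    """Shortest directed path lengths from ``source`` (breadth-first).

    Each node is visited at most once; cycles terminate naturally.
    """
    return nx.single_source_shortest_path_length(
        net.digraph(), source, cutoff=max_depth
    )


def downstream_targets(
    net: InteractionNetwork,
    regulator: str,
    universe: ReferenceUniverse,
    max_depth: Optional[int] = None,
) -> TargetAttribution:
    """Trace the dependency graph of ``regulator`` and attribute its targets.

    Returns the attribution with ``full_targets`` = all measured nodes
    (members of ``universe``) reachable by a directed path of length
    <= ``max_depth`` (unlimited when None), the regulator itself excluded,
    together with the shortest-path distance of each.
    """
    _require_node(net, regulator, "regulator")
    dist = _bfs_distances(net, regulator, max_depth)
    targets = {
        n: d for n, d in dist.items() if n != regulator and n in universe.ids
    }
    return TargetAttribution(
        regulator=regulator,
        full_targets=frozenset(targets),
        distances=targets,
    )


def exclude_competitor(
    attr: TargetAttribution, net: InteractionNetwork, competitor: str
) -> frozenset[str]:
    """Reduce a regulator's target set by a competing regulator.

    A target n is dropped when d(competitor, n) <= d(regulator, n), where
    distances are unweighted shortest directed path lengths and an
    unreachable target counts as infinitely far.  The reduced set is cached
    in ``attr.per_competitor`` and returned.
    """
    if competitor == attr.regulator:
        raise ValueError("competitor must differ from the regulator")
    _require_node(net, competitor, "competitor")
    comp_dist = _bfs_distances(net, competitor)
    kept = frozenset(
        n
        for n in attr.full_targets
        if comp_dist.get(n, None) is None or comp_dist[n] > attr.distances[n]
    )
    attr.per_competitor[competitor] = kept
    return kept


def candidate_competitors(
    net: InteractionNetwork,
    attr: TargetAttribution,
    max_candidates: int = 50,
) -> list[str]:
    """Regulator nodes whose downstream reach overlaps the attributed targets.

    Candidates are nodes with out-degree >= 1 (other than the regulator)
    whose own downstream closure shares at least one member with
    ``attr.full_targets``, ordered by descending shared-target count with
    lexicographic tie-break, truncated to ``max_candidates``.
    """
    if max_candidates < 1:
        raise ValueError("max_candidates must be positive")
    shared: list[tuple[int, str]] = []
    targets = attr.full_targets
    for node in net.out_degree_nodes():
        if node == attr.regulator:
            continue
        reach = _bfs_distances(net, node)
        count = sum(1 for t in targets if t in reach and t != node)
        if count >= 1:
            shared.append((count, node))
    shared.sort(key=lambda item: (-item[0], item[1]))
    return [node for _, node in shared[:max_candidates]]


def direct_targets(
    net: InteractionNetwork, regulator: str, ds: DifferentialSet
) -> set[str]:
    """Differentially expressed one-step transcriptional targets.

    One-step successors of ``regulator`` via transcriptional_regulation
    edges, intersected with the DE genes/proteins (up or down) of ``ds``.
    """
    _require_node(net, regulator, "regulator")
    succ = net.successors(regulator, InteractionType.transcriptional_regulation)
    return succ & ds.de_all
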