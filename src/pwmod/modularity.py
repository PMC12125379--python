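"""Deterministic modularity and the per-community edge trisection.

Two algebraically equivalent formulations of Newman modularity are provided:

* the adjacency form, Q = (1/2M) sum_ij (A_ij - k_i k_j / 2M) delta(x_i, x_j),
  computed literally from the adjacency structure; and
* the community (edge-count) form,
  Q = sum_c [ |e_c|/m - ((2|e_c| + |e_{c,cbar}|) / (2m))^2 ],
  driven by the trisection of the edge set that each community c induces:
  within edges e_c, cross edges e_{c,cbar}, and outside edges e_cbar.

The community form is the one the partition algorithm builds on, because each
community's contribution depends only on the three edge counts, not on which
particular edges are present.  The empty world (m = 0) has modularity 0 by
convention; both formulations are 0/0 there and a single shared convention
keeps brute force, partitioning, and sampling mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import Clustering, DeterministicNetwork, Edge, ProbabilisticNetwork

__all__ = [
    "EdgeTrisection",
    "edge_trisection",
    "modularity_communities",
    "modularity_adjacency",
    "weighted_modularity",
]


@dataclass(frozen=True)
class EdgeTrisection:
    """Split of all edges relative to one community c.

    ``within``: both endpoints in c; ``cross``: exactly one endpoint in c;
    ``outside``: neither endpoint in c.  Capacities T_x, T_y, T_z are the
    sizes of the three parts and always sum to m.
    """

    community: str
    within: tuple[Edge, ...]
    cross: tuple[Edge, ...]
    outside: tuple[Edge, ...]

    @property
    def t_x(self) -> int:
        return len(self.within)

    @property
    def t_y(self) -> int:
        return len(self.cross)

    @property
    def t_z(self) -> int:
        return len(self.outside)


def edge_trisection(
    network: ProbabilisticNetwork | DeterministicNetwork,
    clustering: Clustering,
    community: str,
) -> EdgeTrisection:
    """Partition the network's edges into within/cross/outside for one community."""
    if community not in clustering.communities:
        raise KeyError(f"unknown community label {community!r}")
    assignment = clustering.assignment
    within, cross, outside = [], [], []
    for u, v in network.edges:
        inside = (assignment[u] == community) + (assignment[v] == community)
        if inside == 2:
            within.append((u, v))
        elif inside == 1:
            cross.append((u, v))
        else:
            outside.append((u, v))
    return EdgeTrisection(
        community=community,
        within=tuple(within),
        cross=tuple(cross),
        outside=tuple(outside),
    )


def modularity_communities(world: DeterministicNetwork, clustering: Clustering) -> float:
    """Community-form modularity of a deterministic world; 0 for the empty world."""
    m = world.m
    if m == 0:
        return 0.0
    assignment = clustering.assignment
    x: dict[str, int] = {c: 0 for c in clustering.communities}
    y: dict[str, int] = {c: 0 for c in clustering.communities}
    for u, v in world.edges:
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            x[cu] += 1
        else:
            y[cu] += 1
            y[cv] += 1
    q = 0.0
    for c in clustering.communities:
        q += x[c] / m - ((2 * x[c] + y[c]) / (2 * m)) ** 2
    return q


def modularity_adjacency(world: DeterministicNetwork, clustering: Clustering) -> float:
    """Adjacency-form modularity, evaluated pair-by-pair within communities.

    Runs the double sum over ordered node pairs (i, j) with delta(x_i, x_j),
    i.e. over ordered pairs inside each community (A_ii = 0: simple graph).
    Kept as a structurally independent cross-check of the community form.
    """
    m = world.m
    if m == 0:
        return 0.0
    adj: dict[str, set[str]] = {node: set() for node in world.nodes}
    degree: dict[str, int] = {node: 0 for node in world.nodes}
    for u, v in world.edges:
        adj[u].add(v)
        adj[v].add(u)
        degree[u] += 1
        degree[v] += 1
    two_m = 2.0 * m
    total = 0.0
    for label in clustering.communities:
        members = clustering.members(label)
        for i in members:
            for j in members:
                a_ij = 1.0 if j in adj[i] else 0.0
                total += a_ij - degree[i] * degree[j] / two_m
    return total / two_m


def weighted_modularity(network: ProbabilisticNetwork, clustering: Clustering) -> float:
    """Modularity of the probabilistic network read as a weighted graph.

    The standard weighted generalisation: A_ij = p_ij, M = total edge weight,
    k_i = node strength.  Because weights enter only relative to their total,
    scaling all probabilities by a common factor leaves the value unchanged —
    which is exactly why weighting cannot stand in for expected modularity.
    """
    if network.m == 0:
        return 0.0
    assignment = clustering.assignment
    total_w = 0.0
    within_w: dict[str, float] = {c: 0.0 for c in clustering.communities}
    strength_sum: dict[str, float] = {c: 0.0 for c in clustering.communities}
    for (u, v), p in network.prob.items():
        total_w += p
        if assignment[u] == assignment[v]:
            within_w[assignment[u]] += p
        strength_sum[assignment[u]] += p
        strength_sum[assignment[v]] += p
    q = 0.0
    for c in clustering.communities:
        q += within_w[c] / total_w - (strength_sum[c] / (2.0 * total_w)) ** 2
    return q
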