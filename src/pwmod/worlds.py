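"""Exact brute-force machinery over possible worlds.

A probabilistic network with m edges generates 2^m deterministic worlds, one
per edge subset, with independent-edge probabilities

    Pr(G) = prod_{e in E_G} p(e) * prod_{e in E \\ E_G} (1 - p(e)).

Expected modularity is the probability-weighted mean of the modularity of
every world.  This module enumerates all worlds explicitly and is the
correctness oracle for the partition algorithm; it is exponential in m and
refuses inputs above a configurable cap.

Implementation note: worlds are indexed by bitmasks over the canonical sorted
edge order.  World probabilities and per-community present-edge counts are
built by array doubling (append one edge at a time, duplicating the arrays
for the absent/present branch), which yields exact products and exact integer
counts for all 2^m worlds without a Python-level loop over worlds.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .modularity import edge_trisection
from .network import Clustering, DeterministicNetwork, ProbabilisticNetwork
from .results import ExpectedModularityResult

__all__ = [
    "ModularityDistribution",
    "world_probability",
    "enumerate_worlds",
    "brute_force_expected_modularity",
    "brute_force_modularity_distribution",
    "IntractableError",
    "DEFAULT_MAX_EDGES",
]

DEFAULT_MAX_EDGES = 25


class IntractableError(ValueError):
    """Raised when brute-force enumeration is refused as too large."""


@dataclass(frozen=True)
class ModularityDistribution:
    """Discrete distribution of modularity over the 2^m possible worlds.

    ``support`` holds the distinct modularity values (ascending) and ``mass``
    their probabilities; values closer than the merge tolerance are pooled.
    """

    support: np.ndarray
    mass: np.ndarray

    @property
    def expectation(self) -> float:
        return float(np.dot(self.support, self.mass))


def world_probability(network: ProbabilisticNetwork, world: DeterministicNetwork) -> float:
    """Independent-edge probability of observing one particular world."""
    present = set(world.edges)
    for e in present:
        if e not in network.prob:
            raise ValueError(f"world edge {e!r} is not an edge of the network")
    prob = 1.0
    for e in network.edges:
        p = network.prob[e]
        prob *= p if e in present else (1.0 - p)
    return prob


def _check_cap(m: int, max_edges: int) -> None:
    if m > max_edges:
        raise IntractableError(
            f"brute force over 2^{m} worlds refused (cap {max_edges} edges); "
            "use the FPWP method instead"
        )


def enumerate_worlds(
    network: ProbabilisticNetwork,
    clustering: Clustering,
    max_edges: int = DEFAULT_MAX_EDGES,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (probability, modularity) arrays indexed by world bitmask.

    Bit i of the index corresponds to edge i in canonical sorted order.
    """
    m = network.m
    _check_cap(m, max_edges)
    probs = network.probabilities()

    # Exact world probabilities by doubling: absent branch then present branch.
    pr = np.array([1.0])
    for p in probs:
        pr = np.concatenate([pr * (1.0 - p), pr * p])

    n_worlds = 1 << m
    if m == 0:
        return pr, np.zeros(1)

    # total present-edge count per world, by the same doubling
    total = np.zeros(1, dtype=np.int32)
    for _ in range(m):
        total = np.concatenate([total, total + 1])

    q = np.zeros(n_worlds)
    with np.errstate(divide="ignore", invalid="ignore"):
        m_w = total.astype(np.float64)
        for c in clustering.communities:
            tri = edge_trisection(network, clustering, c)
            within = set(tri.within)
            cross = set(tri.cross)
            x = np.zeros(1, dtype=np.int32)
            y = np.zeros(1, dtype=np.int32)
            for e in network.edges:
                dx = 1 if e in within else 0
                dy = 1 if e in cross else 0
                x = np.concatenate([x, x + dx])
                y = np.concatenate([y, y + dy])
            term = x / m_w - ((2.0 * x + y) / (2.0 * m_w)) ** 2
            term[total == 0] = 0.0  # empty-world convention
            q += term
    return pr, q


def brute_force_expected_modularity(
    network: ProbabilisticNetwork,
    clustering: Clustering,
    max_edges: int = DEFAULT_MAX_EDGES,
) -> ExpectedModularityResult:
    """E(Q) as the exact sum over all 2^m worlds."""
    start = time.perf_counter()
    pr, q = enumerate_worlds(network, clustering, max_edges=max_edges)
    value = float(np.dot(pr, q))
    return ExpectedModularityResult(
        method="brute",
        value=value,
        diagnostics={
            "worlds": int(pr.size),
            "probability_mass": float(pr.sum()),
            "elapsed": time.perf_counter() - start,
        },
    )


def brute_force_modularity_distribution(
    network: ProbabilisticNetwork,
    clustering: Clustering,
    max_edges: int = DEFAULT_MAX_EDGES,
    merge_tol: float = 1e-12,
) -> ModularityDistribution:
    """Full distribution of Q, pooling worlds whose Q differ by < merge_tol."""
    pr, q = enumerate_worlds(network, clustering, max_edges=max_edges)
    order = np.argsort(q, kind="stable")
    q_sorted = q[order]
    pr_sorted = pr[order]
    if q_sorted.size == 0:
        return ModularityDistribution(support=np.array([]), mass=np.array([]))
    # group boundaries where consecutive sorted values differ beyond tolerance
    breaks = np.flatnonzero(np.diff(q_sorted) > merge_tol) + 1
    groups = np.split(np.arange(q_sorted.size), breaks)
    support = np.array([q_sorted[g[0]] for g in groups])
    mass = np.array([pr_sorted[g].sum() for g in groups])
    keep = mass > 0.0  # drop impossible worlds (e.g. an absent p=1 edge)
    return ModularityDistribution(support=support[keep], mass=mass[keep])
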