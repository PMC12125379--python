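"""Comparison methods: Monte Carlo sampling and thresholding.

Sampling draws whole possible worlds — each edge included independently with
its probability — and averages the deterministic modularity of the draws.
The estimator is unbiased for E(Q); its variance, and hence convergence,
worsens with network uncertainty (entropy) and with less pronounced
community structure.

Thresholding keeps exactly the edges with p >= t and reports the
deterministic modularity of that single world.  It is accurate only when the
network is almost deterministic (all probabilities near 0 or 1).

RNG policy: all randomness flows through ``numpy.random.default_rng(seed)``.
Sample t of a run consumes uniforms [t*m, (t+1)*m) of the stream, in
canonical edge order, so single-world draws and batched runs with the same
seed see identical worlds.
"""

from __future__ import annotations

import time

import numpy as np

from .modularity import modularity_communities
from .network import Clustering, DeterministicNetwork, ProbabilisticNetwork
from .results import SamplingResult

__all__ = [
    "sample_world",
    "sampling_expected_modularity",
    "sampling_time_budget",
    "threshold_expected_modularity_estimate",
]


def sample_world(
    network: ProbabilisticNetwork, rng: np.random.Generator
) -> DeterministicNetwork:
    """Draw one possible world: edge e kept iff u_e < p_e, canonical order."""
    u = rng.random(network.m)
    p = np.array(network.probabilities())
    present = [e for e, keep in zip(network.edges, u < p) if keep]
    return DeterministicNetwork(nodes=network.nodes, edges=tuple(present))


def _community_indicators(
    network: ProbabilisticNetwork, clustering: Clustering
) -> tuple[np.ndarray, np.ndarray]:
    """(m, k) 0/1 matrices flagging each edge as within / cross per community."""
    k = clustering.k
    within = np.zeros((network.m, k))
    cross = np.zeros((network.m, k))
    index = {c: i for i, c in enumerate(clustering.communities)}
    for row, (u, v) in enumerate(network.edges):
        cu, cv = clustering.assignment[u], clustering.assignment[v]
        if cu == cv:
            within[row, index[cu]] = 1.0
        else:
            cross[row, index[cu]] = 1.0
            cross[row, index[cv]] = 1.0
    return within, cross


def _batch_modularity(
    draws: np.ndarray, within: np.ndarray, cross: np.ndarray
) -> np.ndarray:
    """Community-form modularity of each row of a (theta, m) 0/1 draw matrix."""
    x = draws @ within  # (theta, k) present within-edge counts
    y = draws @ cross
    m_w = draws.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = x / m_w - ((2.0 * x + y) / (2.0 * m_w)) ** 2
    q = np.where(m_w[:, 0] > 0, np.nansum(terms, axis=1), 0.0)
    return q


def sampling_expected_modularity(
    network: ProbabilisticNetwork,
    clustering: Clustering,
    theta: int,
    seed: int,
    keep_samples: bool = False,
) -> SamplingResult:
    """Mean modularity over ``theta`` independently sampled worlds."""
    if theta < 1:
        raise ValueError(f"theta must be >= 1, got {theta}")
    start = time.perf_counter()
    rng = np.random.default_rng(seed)
    p = np.array(network.probabilities())
    within, cross = _community_indicators(network, clustering)
    draws = (rng.random((theta, network.m)) < p).astype(np.float64)
    q = _batch_modularity(draws, within, cross)
    return SamplingResult(
        estimate=float(q.mean()),
        theta=theta,
        seed=seed,
        elapsed=time.perf_counter() - start,
        per_sample=tuple(q.tolist()) if keep_samples else None,
    )


def sampling_time_budget(
    network: ProbabilisticNetwork,
    clustering: Clustering,
    budget: float,
    seed: int,
    chunk: int = 100,
) -> SamplingResult:
    """Sample until the wall-clock budget elapses; at least one world is drawn."""
    if budget <= 0:
        raise ValueError(f"budget must be positive, got {budget!r}")
    start = time.perf_counter()
    rng = np.random.default_rng(seed)
    p = np.array(network.probabilities())
    within, cross = _community_indicators(network, clustering)
    total = 0.0
    theta = 0
    size = 1  # first chunk is a single sample so tiny budgets still report one
    while True:
        draws = (rng.random((size, network.m)) < p).astype(np.float64)
        q = _batch_modularity(draws, within, cross)
        total += float(q.sum())
        theta += size
        if time.perf_counter() - start >= budget:
            break
        size = chunk
    return SamplingResult(
        estimate=total / theta,
        theta=theta,
        seed=seed,
        elapsed=time.perf_counter() - start,
    )


def threshold_expected_modularity_estimate(
    network: ProbabilisticNetwork,
    clustering: Clustering,
    threshold: float,
) -> float:
    """Deterministic modularity of the world keeping exactly the edges with p >= t."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold!r} outside (0, 1]")
    kept = tuple(e for e in network.edges if network.prob[e] >= threshold)
    world = DeterministicNetwork(nodes=network.nodes, edges=kept)
    return modularity_communities(world, clustering)
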