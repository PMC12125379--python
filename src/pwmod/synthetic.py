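"""Generators for the experimental inputs: topologies and edge probabilities.

Topologies: planted-partition (stochastic block model) networks with (k, nc,
p_in, p_out), plus Erdős–Rényi, Barabási–Albert, Watts–Strogatz small-world
and a hand-rolled forest-fire model.  Probability assignment is either
uniform (one value for every edge) or entropy-targeted: probabilities spread
around the uniform value whose binary entropy equals the target, with the
centre adjusted so the realised entropy ratio matches the target closely.

Node identifiers are zero-padded strings ("v0000", ...) so lexicographic and
numeric orders coincide; community labels are "c0", "c1", ....  All
generators are deterministic functions of their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .entropy import binary_entropy
from .network import Clustering, DeterministicNetwork, ProbabilisticNetwork

__all__ = [
    "PlantedPartitionSpec",
    "generate_planted_partition",
    "generate_topology",
    "random_clustering",
    "dirichlet_clustering",
    "assign_edge_probabilities",
]

MIN_EDGE_PROBABILITY = 1e-3  # assigned probabilities stay strictly positive


def _node_name(i: int) -> str:
    return f"v{i:05d}"


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Parameters of a planted-partition (SBM) topology.

    ``k`` communities of ``nc`` nodes each; each within-community pair is an
    edge with probability ``p_in``, each cross pair with ``p_out``.
    """

    k: int
    nc: int
    p_in: float
    p_out: float
    seed: int

    def __post_init__(self):
        if self.k < 1 or self.nc < 1:
            raise ValueError("k and nc must be >= 1")
        if not (0.0 <= self.p_in <= 1.0 and 0.0 <= self.p_out <= 1.0):
            raise ValueError("densities must lie in [0, 1]")


def _from_nx(graph: nx.Graph) -> DeterministicNetwork:
    mapping = {node: _node_name(i) for i, node in enumerate(sorted(graph.nodes()))}
    edges = [(mapping[u], mapping[v]) for u, v in graph.edges()]
    return DeterministicNetwork.from_edges(edges, extra_nodes=mapping.values())


def generate_planted_partition(
    spec: PlantedPartitionSpec,
) -> tuple[DeterministicNetwork, Clustering]:
    """Planted-partition topology plus its ground-truth clustering."""
    graph = nx.planted_partition_graph(
        spec.k, spec.nc, spec.p_in, spec.p_out, seed=spec.seed
    )
    topo = _from_nx(graph)
    assignment = {
        _node_name(i): f"c{i // spec.nc}" for i in range(spec.k * spec.nc)
    }
    return topo, Clustering.from_mapping(assignment)


def _forest_fire(n: int, seed: int, forward_prob: float = 0.37) -> nx.Graph:
    """Undirected forest-fire growth: each newcomer links an ambassador and
    recursively 'burns' a geometric number of each burning node's neighbours."""
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    graph.add_node(0)
    for new in range(1, n):
        ambassador = int(rng.integers(new))
        burned = {ambassador}
        frontier = [ambassador]
        while frontier:
            node = frontier.pop()
            neighbours = [w for w in graph.neighbors(node) if w not in burned]
            if not neighbours:
                continue
            # geometric number of spreads with mean fwd/(1-fwd)
            n_burn = min(len(neighbours), rng.geometric(1.0 - forward_prob) - 1)
            if n_burn <= 0:
                continue
            chosen = rng.choice(len(neighbours), size=n_burn, replace=False)
            for idx in sorted(int(c) for c in chosen):
                burned.add(neighbours[idx])
                frontier.append(neighbours[idx])
        graph.add_node(new)
        for target in sorted(burned):
            graph.add_edge(new, target)
    return graph


def generate_topology(
    model: str,
    n: int,
    target_m: int,
    seed: int,
    ba_attachment: int | None = None,
    sw_rewire: float = 0.1,
    ffn_forward: float = 0.37,
) -> DeterministicNetwork:
    """Random simple undirected topology with approximately ``target_m`` edges.

    Models: ``er`` (G(n, p) with p tuned to the target), ``ba`` (preferential
    attachment; m = a*(n - a) exactly for attachment a), ``sw``
    (Watts–Strogatz ring with rewiring; m = n * round(target degree)/2), and
    ``ffn`` (forest fire; edge count only loosely controlled by the forward
    burning probability).
    """
    model = model.lower()
    if n < 2:
        raise ValueError("n must be >= 2")
    max_m = n * (n - 1) // 2
    if target_m > max_m:
        raise ValueError(f"target_m={target_m} exceeds the {max_m} possible pairs")
    if model == "er":
        graph = nx.gnp_random_graph(n, target_m / max_m, seed=seed)
    elif model == "ba":
        a = ba_attachment if ba_attachment is not None else max(1, round(target_m / n))
        if not 1 <= a < n:
            raise ValueError(f"attachment {a} not in [1, n)")
        graph = nx.barabasi_albert_graph(n, a, seed=seed)
    elif model == "sw":
        k_ring = max(2, 2 * round(target_m / n))
        if k_ring >= n:
            raise ValueError(f"target_m={target_m} unreachable for a ring of {n} nodes")
        graph = nx.watts_strogatz_graph(n, k_ring, sw_rewire, seed=seed)
    elif model == "ffn":
        graph = _forest_fire(n, seed=seed, forward_prob=ffn_forward)
    else:
        raise ValueError(f"unknown topology model {model!r} (er|ba|sw|ffn)")
    return _from_nx(graph)


def random_clustering(
    topology: DeterministicNetwork, k: int, seed: int
) -> Clustering:
    """Assign nodes to k communities uniformly at random (every label used)."""
    if k < 1 or k > topology.n:
        raise ValueError(f"k={k} outside 1..{topology.n}")
    rng = np.random.default_rng(seed)
    labels = rng.integers(k, size=topology.n)
    # guarantee every community is non-empty
    forced = rng.choice(topology.n, size=k, replace=False)
    for j, node_idx in enumerate(sorted(int(i) for i in forced)):
        labels[node_idx] = j
    assignment = {node: f"c{labels[i]}" for i, node in enumerate(topology.nodes)}
    return Clustering.from_mapping(assignment)


def dirichlet_clustering(
    topology: DeterministicNetwork, k: int, concentration: float, seed: int
) -> Clustering:
    """k communities with sizes drawn from a Dirichlet split of the nodes.

    Small ``concentration`` gives highly unequal community sizes, large gives
    near-equal ones — the knob for the size-variance runtime study.
    """
    if k < 1 or k > topology.n:
        raise ValueError(f"k={k} outside 1..{topology.n}")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet([concentration] * k)
    sizes = np.maximum(1, np.round(weights * topology.n).astype(int))
    while sizes.sum() > topology.n:
        sizes[int(np.argmax(sizes))] -= 1
    while sizes.sum() < topology.n:
        sizes[int(np.argmin(sizes))] += 1
    order = rng.permutation(topology.n)
    assignment = {}
    pos = 0
    for j, size in enumerate(sizes):
        for idx in order[pos : pos + size]:
            assignment[topology.nodes[int(idx)]] = f"c{j}"
        pos += size
    return Clustering.from_mapping(assignment)


def assign_edge_probabilities(
    topology: DeterministicNetwork,
    scheme: str,
    seed: int = 0,
    p: float | None = None,
    target: float | None = None,
    spread: float = 0.15,
    tolerance: float = 0.02,
) -> ProbabilisticNetwork:
    """Attach existence probabilities to a deterministic topology.

    ``scheme='uniform'`` gives every edge probability ``p``.

    ``scheme='entropy_target'`` draws probabilities uniformly in a band of
    half-width ``spread`` around a centre on the high branch (p >= 0.5), then
    bisects the centre so the realised entropy ratio matches ``target``;
    if the spread makes the target unreachable it is halved until the
    realised ratio is within ``tolerance``.
    """
    if topology.m == 0:
        raise ValueError("cannot assign probabilities to a network with no edges")
    if scheme == "uniform":
        if p is None or not 0.0 < p <= 1.0:
            raise ValueError(f"uniform scheme needs p in (0, 1], got {p!r}")
        probs = np.full(topology.m, p)
    elif scheme == "entropy_target":
        if target is None or not 0.0 <= target <= 1.0:
            raise ValueError(f"entropy_target scheme needs target in [0, 1], got {target!r}")
        probs = _entropy_targeted_probs(topology.m, target, spread, tolerance, seed)
    else:
        raise ValueError(f"unknown scheme {scheme!r} (uniform|entropy_target)")
    return ProbabilisticNetwork.from_edges(
        {e: float(q) for e, q in zip(topology.edges, probs)},
        extra_nodes=topology.nodes,
    )


def _entropy_targeted_probs(
    m: int, target: float, spread: float, tolerance: float, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-1.0, 1.0, size=m)

    def realized(center: float, width: float) -> tuple[np.ndarray, float]:
        probs = np.clip(center + width * offsets, MIN_EDGE_PROBABILITY, 1.0)
        return probs, float(np.mean(binary_entropy(probs)))

    width = spread
    while True:
        # mean entropy decreases as the centre moves from 0.5 towards 1
        lo, hi = 0.5, 1.0 + width
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            _, ratio = realized(mid, width)
            if ratio > target:
                lo = mid
            else:
                hi = mid
        probs, ratio = realized(0.5 * (lo + hi), width)
        if abs(ratio - target) <= tolerance or width < 1e-9:
            break
        width *= 0.5
    if abs(ratio - target) > tolerance:
        raise ValueError(
            f"could not realise entropy ratio {target} within {tolerance} "
            f"(achieved {ratio:.4f})"
        )
    return probs
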