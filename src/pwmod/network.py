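"""Data model for probabilistic networks, deterministic worlds, and clusterings.

A probabilistic network is an undirected simple graph G = (V, E, p) whose
edges carry independent existence probabilities p : E -> (0, 1].  Under
possible-world semantics the network is a generative model for 2^m
deterministic networks ("worlds"), one per edge subset.  A clustering is a
total assignment of nodes to community labels; it is the input partition for
which expected modularity is computed.

Node identifiers are opaque strings.  All iteration is over the sorted order
of identifiers (and lexicographically sorted canonical edge pairs), so
enumeration and seeding are reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Edge",
    "ProbabilisticNetwork",
    "DeterministicNetwork",
    "Clustering",
    "ValidationReport",
    "NetworkFormatError",
    "CoverageError",
    "canonical_edge",
    "read_probabilistic_edge_list",
    "write_probabilistic_edge_list",
    "read_clustering",
    "write_clustering",
    "write_deterministic_edge_list",
    "validate",
]

Edge = tuple[str, str]


class NetworkFormatError(ValueError):
    """Raised for malformed edge-list or clustering files."""


class CoverageError(ValueError):
    """Raised when a clustering does not cover exactly the network's nodes."""

    def __init__(self, message: str, missing: Sequence[str] = (), extra: Sequence[str] = ()):
        super().__init__(message)
        self.missing = tuple(missing)
        self.extra = tuple(extra)


def canonical_edge(u: str, v: str) -> Edge:
    """Return the unordered pair (u, v) as a lexicographically sorted tuple."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class ProbabilisticNetwork:
    """Undirected simple graph with a per-edge existence probability in (0, 1].

    ``nodes`` is the sorted node list (isolated nodes permitted); ``edges``
    the sorted list of canonical pairs; ``prob`` maps each edge to its
    probability.
    """

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    prob: Mapping[Edge, float]

    @classmethod
    def from_edges(
        cls,
        edge_probs: Mapping[Edge, float] | Iterable[tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
    ) -> "ProbabilisticNetwork":
        if isinstance(edge_probs, Mapping):
            items = [(u, v, p) for (u, v), p in edge_probs.items()]
        else:
            items = [(u, v, p) for u, v, p in edge_probs]
        prob: dict[Edge, float] = {}
        nodes = set(extra_nodes)
        for u, v, p in items:
            u, v = str(u), str(v)
            if u == v:
                raise NetworkFormatError(f"self-loop on node {u!r} is not allowed")
            e = canonical_edge(u, v)
            if e in prob:
                raise NetworkFormatError(f"duplicate edge {e[0]!r}-{e[1]!r}")
            p = float(p)
            if not 0.0 < p <= 1.0:
                raise NetworkFormatError(
                    f"probability {p!r} for edge {e[0]!r}-{e[1]!r} out of range (0,1]"
                )
            prob[e] = p
            nodes.add(u)
            nodes.add(v)
        edges = tuple(sorted(prob))
        return cls(nodes=tuple(sorted(str(x) for x in nodes)), edges=edges, prob=prob)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    def probabilities(self) -> list[float]:
        """Edge probabilities in canonical edge order."""
        return [self.prob[e] for e in self.edges]

    def full_world(self) -> "DeterministicNetwork":
        return DeterministicNetwork(nodes=self.nodes, edges=self.edges)

    def world(self, present: Iterable[Edge]) -> "DeterministicNetwork":
        """Deterministic world containing exactly the given subset of edges."""
        present = tuple(sorted(canonical_edge(*e) for e in present))
        edge_set = set(self.edges)
        for e in present:
            if e not in edge_set:
                raise ValueError(f"edge {e!r} is not an edge of the network")
        return DeterministicNetwork(nodes=self.nodes, edges=present)


@dataclass(frozen=True)
class DeterministicNetwork:
    """A single possible world: a concrete edge subset on a fixed node set."""

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "DeterministicNetwork":
        nodes = set(extra_nodes)
        canon = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise NetworkFormatError(f"self-loop on node {u!r} is not allowed")
            canon.add(canonical_edge(u, v))
            nodes.add(u)
            nodes.add(v)
        return cls(nodes=tuple(sorted(nodes)), edges=tuple(sorted(canon)))

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class Clustering:
    """Total assignment of nodes to community labels (the input partition)."""

    assignment: Mapping[str, str]
    communities: tuple[str, ...] = field(default=())

    def __post_init__(self):
        labels = tuple(sorted(set(self.assignment.values())))
        object.__setattr__(self, "communities", labels)

    @classmethod
    def from_mapping(cls, assignment: Mapping[str, str]) -> "Clustering":
        return cls(assignment={str(k): str(v) for k, v in assignment.items()})

    @property
    def k(self) -> int:
        return len(self.communities)

    def members(self, label: str) -> tuple[str, ...]:
        if label not in self.communities:
            raise KeyError(f"unknown community label {label!r}")
        return tuple(sorted(n for n, c in self.assignment.items() if c == label))

    def sizes(self) -> dict[str, int]:
        out = {c: 0 for c in self.communities}
        for c in self.assignment.values():
            out[c] += 1
        return out


@dataclass(frozen=True)
class ValidationReport:
    n: int
    m: int
    k: int
    community_sizes: dict[str, int]


def _data_lines(path: str | Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_probabilistic_edge_list(
    path: str | Path, delimiter: str | None = None
) -> ProbabilisticNetwork:
    """Read ``u v p`` lines (whitespace-separated by default, ``#`` comments).

    Rejects self-loops, duplicate pairs (in either order), and probabilities
    outside (0, 1], reporting the offending line number.
    """
    triples: list[tuple[str, str, float]] = []
    seen: dict[Edge, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split(delimiter)
        if len(fields) < 3:
            raise NetworkFormatError(f"{path}:{lineno}: expected 'u v p', got {line!r}")
        u, v, p_str = fields[0], fields[1], fields[2]
        try:
            p = float(p_str)
        except ValueError:
            raise NetworkFormatError(
                f"{path}:{lineno}: unparseable probability {p_str!r}"
            ) from None
        if u == v:
            raise NetworkFormatError(f"{path}:{lineno}: self-loop on node {u!r}")
        e = canonical_edge(u, v)
        if e in seen:
            raise NetworkFormatError(
                f"{path}:{lineno}: duplicate edge {u!r}-{v!r} (first seen on line {seen[e]})"
            )
        if not 0.0 < p <= 1.0:
            raise NetworkFormatError(
                f"{path}:{lineno}: probability {p} out of range (0,1]"
            )
        seen[e] = lineno
        triples.append((u, v, p))
    return ProbabilisticNetwork.from_edges(triples)


def write_probabilistic_edge_list(
    network: ProbabilisticNetwork, path: str | Path, delimiter: str = "\t"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in network.edges:
            fh.write(f"{u}{delimiter}{v}{delimiter}{network.prob[(u, v)]!r}\n")


def write_deterministic_edge_list(
    world: DeterministicNetwork, path: str | Path, delimiter: str = "\t"
) -> None:
    """Plain two-column edge list (no probability column) for a world."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in world.edges:
            fh.write(f"{u}{delimiter}{v}\n")


def read_clustering(path: str | Path, delimiter: str | None = None) -> Clustering:
    """Read ``node label`` lines; labels are kept verbatim."""
    assignment: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise NetworkFormatError(f"{path}:{lineno}: expected 'node label', got {line!r}")
        node, label = fields[0], fields[1]
        if node in assignment and assignment[node] != label:
            raise NetworkFormatError(
                f"{path}:{lineno}: conflicting assignment for node {node!r} "
                f"({assignment[node]!r} vs {label!r})"
            )
        assignment[node] = label
    return Clustering.from_mapping(assignment)


def write_clustering(clustering: Clustering, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for node in sorted(clustering.assignment):
            fh.write(f"{node}{delimiter}{clustering.assignment[node]}\n")


def validate(
    network: ProbabilisticNetwork | DeterministicNetwork, clustering: Clustering
) -> ValidationReport:
    """Check that the clustering covers exactly the network's nodes.

    Returns a summary report (n, m, k, community sizes) on success; raises
    :class:`CoverageError` naming the offending nodes otherwise.
    """
    net_nodes = set(network.nodes)
    clu_nodes = set(clustering.assignment)
    missing = sorted(net_nodes - clu_nodes)
    extra = sorted(clu_nodes - net_nodes)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"uncovered nodes: {missing}")
        if extra:
            parts.append(f"nodes not in network: {extra}")
        raise CoverageError("; ".join(parts), missing=missing, extra=extra)
    return ValidationReport(
        n=network.n, m=network.m, k=clustering.k, community_sizes=clustering.sizes()
    )
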