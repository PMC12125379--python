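"""Shared test helpers: random brute-forceable problem instances."""

from pwmod import (
    PlantedPartitionSpec,
    assign_edge_probabilities,
    edge_trisection,
    generate_planted_partition,
)


def make_random_instance(seed, k=3, nc=3, p_in=0.8, p_out=0.05, entropy=0.6,
                         min_m=4, max_m=12, max_part=20):
    """Small planted-partition probabilistic network suitable for brute force.

    Returns None when the drawn topology misses the edge-count window or has
    a trisection part beyond the subset-enumeration guard.
    """
    spec = PlantedPartitionSpec(k=k, nc=nc, p_in=p_in, p_out=p_out, seed=seed)
    topology, clustering = generate_planted_partition(spec)
    if not min_m <= topology.m <= max_m:
        return None
    for c in clustering.communities:
        tri = edge_trisection(topology, clustering, c)
        if max(tri.t_x, tri.t_y, tri.t_z) > max_part:
            return None
    network = assign_edge_probabilities(
        topology, "entropy_target", target=entropy, seed=seed
    )
    return network, clustering


def collect_random_instances(count, start_seed=0, **kwargs):
    out = []
    seed = start_seed
    while len(out) < count:
        inst = make_random_instance(seed, **kwargs)
        if inst is not None:
            out.append(inst)
        seed += 1
        if seed - start_seed > 50 * count:
            raise RuntimeError("could not draw enough instances")
    return out
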