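"""Compare FPWP with sampling, thresholding and weighting on a CCS network.

Generates the clear-community-structure planted-partition network (3
communities of 9 nodes, p_in = 0.99, p_out = 0.01), assigns every edge
probability 0.9 (entropy ratio 0.47), and estimates E(Q) with each method.
FPWP is exact; sampling converges to it; thresholding and weighting land on
deterministic surrogate values that are biased in general.
"""

from pwmod import (
    PlantedPartitionSpec,
    assign_edge_probabilities,
    entropy_ratio,
    expected_modularity_fpwp,
    generate_planted_partition,
    sampling_expected_modularity,
    threshold_expected_modularity_estimate,
    weighted_modularity,
)

topology, clustering = generate_planted_partition(
    PlantedPartitionSpec(k=3, nc=9, p_in=0.99, p_out=0.01, seed=7)
)
network = assign_edge_probabilities(topology, "uniform", p=0.9)
print(f"CCS network: n={network.n}, m={network.m}, "
      f"entropy ratio {entropy_ratio(network):.2f}")

exact = expected_modularity_fpwp(network, clustering)
print(f"\nFPWP (exact):        E(Q) = {exact.value:.6f}")

for theta in (100, 1000, 10000):
    est = sampling_expected_modularity(network, clustering, theta=theta, seed=1)
    print(f"sampling theta={theta:<6d} Q ~ {est.estimate:.6f}  "
          f"(error {abs(est.estimate - exact.value):.2e})")

for t in (0.5, 0.95):
    q = threshold_expected_modularity_estimate(network, clustering, t)
    print(f"threshold t={t:<4}     Q = {q:.6f}  "
          f"(error {abs(q - exact.value):.2e})")

w = weighted_modularity(network, clustering)
print(f"weighted modularity  Q = {w:.6f}  (error {abs(w - exact.value):.2e})")
# Thresholding at t=0.5 keeps every edge (all p=0.9), so it returns the
# deterministic Q of the full topology; weighting ignores the absolute scale
# of the probabilities entirely.  Both differ from E(Q).
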