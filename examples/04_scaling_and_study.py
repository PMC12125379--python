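"""FPWP cost model and the tabulated method-comparison study.

First shows that the work FPWP does — the number of partition cells
sum_c (T_x+1)(T_y+1)(T_z+1) — depends only on the topology and the
clustering, not on the edge probabilities, and grows polynomially with the
edge count.  Then runs the desk-scale comparison study and prints a pivot of
method values by network uncertainty.
"""

import time

from pwmod import (
    assign_edge_probabilities,
    cell_visit_count,
    expected_modularity_fpwp,
    generate_topology,
    random_clustering,
    run_comparison_study,
)

print("FPWP work vs edge count (ER topologies, 5 random communities):")
for m in (100, 200, 400, 800):
    topology = generate_topology("er", n=max(20, m // 3), target_m=m, seed=m)
    clustering = random_clustering(topology, k=5, seed=m + 1)
    network = assign_edge_probabilities(topology, "entropy_target", target=0.4, seed=m)
    start = time.perf_counter()
    result = expected_modularity_fpwp(network, clustering)
    elapsed = time.perf_counter() - start
    assert result.diagnostics["cells"] == cell_visit_count(network, clustering)
    print(f"  m={network.m:4d}  cells={result.diagnostics['cells']:>10,}  "
          f"time {elapsed * 1000:7.1f} ms  E(Q)={result.value:.4f}")

print("\ncomparison study (CCS / LCCS x uniform p in {1.0, 0.9, 0.5}):")
table = run_comparison_study(theta=1000, repeats=3, seed=0)
pivot = table.pivot_table(
    index=["network", "uniform_p"], columns="method", values="value", aggfunc="mean"
)
print(pivot.round(4))
# The sample column is a mean over repeats and tracks fpwp; the weight
# column is constant down each network block; threshold averages over a
# t-grid and departs from fpwp as uniform_p moves away from 1.
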