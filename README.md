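# pwmod — expected modularity in probabilistic networks

Many networks in the life and social sciences are *uncertain*: protein–protein
interactions come with confidence scores, communication links are observed
only intermittently, social ties are inferred with error.  Such systems are
modelled as **probabilistic networks** 𝒢 = (V, E, p), where each edge e
carries an independent existence probability p(e) ∈ (0, 1].  Under
possible-world semantics 𝒢 generates 2^m deterministic graphs ("worlds"),
world w = (V, E_w) having probability

    Pr(w) = ∏_{e ∈ E_w} p(e) · ∏_{e ∈ E∖E_w} (1 − p(e)).

For a **given** clustering 𝒞 of the nodes, modularity Q is then a random
variable, and the natural quality score is its expectation
E(Q) = Σ_w Q_w · Pr(w).  Computing that sum naively costs 2^m modularity
evaluations.  `pwmod` computes it **exactly in polynomial time** and provides
the common approximations for comparison.

## The algorithm

Write modularity per community with the edge *trisection* of community c —
within edges e_c, boundary edges e_{c,c̄}, outside edges e_c̄, of sizes
T_x, T_y, T_z (T_x + T_y + T_z = m):

    Q = Σ_c  |e_c|/m − ((2|e_c| + |e_{c,c̄}|) / 2m)².

A community's term depends only on the three **counts** (x, y, z) of present
edges, not on which edges are present.  Grouping worlds by these counts
partitions the 2^m worlds, per community, into (T_x+1)(T_y+1)(T_z+1) cells
d^{xyz} on which the term is the constant

    Q_c^{xyz} = x/(x+y+z) − ((2x+y) / 2(x+y+z))²,

and, since the three edge sets are disjoint, the cell probability factorises
into three **Poisson-binomial** pmfs (the law of the number of successes in
independent non-identical Bernoulli trials):

    E(Q) = Σ_c Σ_x Σ_y Σ_z  Q_c^{xyz} · Pr(|e_c^w|=x) · Pr(|e_{c,c̄}^w|=y) · Pr(|e_c̄^w|=z).

**PWP** evaluates the pmfs by subset enumeration (exponential, a reference
path); **FPWP** uses the exact DFT closed form of the Poisson-binomial pmf,
giving O(k·m³) total cost that is *independent of the probability values*.
Also included: the brute-force world sum (the oracle), Monte Carlo sampling
of worlds, probability thresholding (keep p ≥ t), weighted modularity
(probabilities as weights), and the entropy ratio
(Σ_e h(p_e))/m ∈ [0, 1] that quantifies network uncertainty.

## Worked example

```python
from pwmod import (Clustering, ProbabilisticNetwork,
                   brute_force_expected_modularity, expected_modularity_fpwp)

network = ProbabilisticNetwork.from_edges({
    ("n1", "n2"): 0.6, ("n2", "n3"): 0.7, ("n2", "n4"): 0.4,
    ("n3", "n4"): 0.5, ("n4", "n5"): 0.8,
})
clustering = Clustering.from_mapping(
    {"n1": "c", "n2": "c", "n3": "rest", "n4": "rest", "n5": "rest"})

print(brute_force_expected_modularity(network, clustering).value)
print(expected_modularity_fpwp(network, clustering).value)
```

prints

```
0.04639822222222222
0.04639822222222221
```

— the exact expected modularity of that 5-edge network, obtained once by
enumerating all 32 worlds and once from 36 partition cells; the values agree
to machine precision because FPWP is an exact reformulation, not an
approximation.  On the 27-node CCS benchmark (three planted communities,
p_in = 0.99, p_out = 0.01, all edge probabilities 0.9, entropy ratio 0.47)
`examples/02_method_comparison.py` prints

```
FPWP (exact):        E(Q) = 0.665902
sampling theta=1000   Q ~ 0.665896  (error 6.26e-06)
threshold t=0.5      Q = 0.666608  (error 7.06e-04)
weighted modularity  Q = 0.666608  (error 7.06e-04)
```

showing sampling converging to the exact value while thresholding and
weighting return the deterministic surrogate instead.

The `examples/` directory holds one short script per capability (exact
computation and the modularity distribution, method comparison, entropy and
sampling convergence, scaling and the tabulated study).  A thin CLI mirrors
the library:

```sh
pwmod generate --model sbm --k 3 --nc 9 --p-in 0.99 --p-out 0.01 \
      --probabilities uniform:0.9 --out-prefix ccs
pwmod inspect --network ccs.edges --clustering ccs.communities
pwmod compute --network ccs.edges --clustering ccs.communities --method fpwp
```

Input formats are plain text: `u v p` edge lists and `node label` clustering
files, whitespace-separated with `#` comments.

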