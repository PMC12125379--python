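"""Entropy ratio of a probabilistic network and its inverse.

The joint entropy of the independent edges is the sum of the binary entropies
h(p_e) = -p_e log2 p_e - (1 - p_e) log2 (1 - p_e); dividing by the edge count
gives the entropy ratio, which lies in [0, 1] in base 2: 0 for a
deterministic network (all p = 1) and 1 when every probability is 0.5.
The pairings used throughout the experiments follow from the closed form:
uniform p = 0.90 gives ratio 0.47 (2 dp), uniform p = 0.50 gives 1.00.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import xlogy

from .network import ProbabilisticNetwork

__all__ = ["binary_entropy", "entropy_ratio", "probability_for_entropy_ratio"]

_LN2 = np.log(2.0)


def binary_entropy(p):
    """h(p) in bits, with the 0 log 0 := 0 convention; vectorised."""
    p = np.asarray(p, dtype=np.float64)
    h = -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / _LN2
    return h if h.ndim else float(h)


def entropy_ratio(network: ProbabilisticNetwork) -> float:
    """Mean per-edge binary entropy of the network, in [0, 1]."""
    if network.m == 0:
        raise ValueError("entropy ratio is undefined for a network with no edges")
    p = np.array(network.probabilities())
    return float(np.sum(binary_entropy(p)) / network.m)


def probability_for_entropy_ratio(target: float, branch: str = "high") -> float:
    """Uniform edge probability whose binary entropy equals ``target``.

    ``branch='high'`` returns the solution p >= 0.5 (the one used to emulate
    mostly-present edges), ``branch='low'`` its mirror 1 - p.  Root found by
    bracketed root-finding to 1e-12.
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target entropy ratio {target!r} outside [0, 1]")
    if branch not in ("high", "low"):
        raise ValueError(f"branch must be 'high' or 'low', got {branch!r}")
    if target == 1.0:
        p = 0.5
    elif target == 0.0:
        p = 1.0
    else:
        p = brentq(lambda q: binary_entropy(q) - target, 0.5, 1.0, xtol=1e-14)
    return p if branch == "high" else 1.0 - p
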