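"""Poisson-binomial pmf engines.

The number of edges present in a fixed edge set, under independent per-edge
probabilities, follows a Poisson-binomial distribution: the law of the number
of successes among independent, non-identically distributed Bernoulli trials.
Three engines compute the same pmf:

``pmf_enumeration``
    The subset-sum definition: pmf[k] sums, over every size-k subset A of the
    trials, the product of p over A and (1 - p) off A.  Exponential in the
    number of trials; kept as the mid-fidelity reference engine.

``pmf_convolution``
    The exact dynamic-programming recurrence: iteratively convolve the
    two-point distributions (1 - p_i, p_i).  O(T^2); the internal cross-check.

``pmf_dft``
    The discrete-Fourier-transform closed form

        pmf[k] = 1/(T+1) * sum_{l=0}^{T} C^{-l k} prod_i (1 + (C^l - 1) p_i),

    with C = exp(2 pi i / (T+1)) — exact in exact arithmetic, O(T^2) for the
    roots-of-unity products.  Tiny negative entries from floating-point noise
    are clamped to zero and the pmf renormalised; a residual off by more than
    1e-8 from unit mass raises, it is never silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CountDistribution",
    "pmf_enumeration",
    "pmf_convolution",
    "pmf_dft",
    "PoissonBinomialNumericalError",
    "ENUMERATION_MAX_TRIALS",
]

ENUMERATION_MAX_TRIALS = 20
_MASS_TOL = 1e-8


class PoissonBinomialNumericalError(ArithmeticError):
    """Raised when a computed pmf fails the unit-mass check beyond tolerance."""


@dataclass(frozen=True)
class CountDistribution:
    """pmf of the success count among independent Bernoulli trials.

    ``probs`` are the trial probabilities (length T); ``pmf`` has length
    T + 1 with pmf[k] = Pr(count = k).
    """

    probs: tuple[float, ...]
    pmf: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.dot(np.arange(self.pmf.size), self.pmf))


def _validate_probs(probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("probs must be one-dimensional")
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("trial probabilities must lie in [0, 1]")
    return p


def _finalize(probs: np.ndarray, pmf: np.ndarray) -> CountDistribution:
    pmf = np.where(pmf < 0.0, np.where(pmf > -_MASS_TOL, 0.0, pmf), pmf)
    if pmf.min() < 0.0:
        raise PoissonBinomialNumericalError(
            f"pmf has a negative entry of magnitude {-pmf.min():.3e}"
        )
    total = pmf.sum()
    if abs(total - 1.0) > _MASS_TOL:
        raise PoissonBinomialNumericalError(
            f"pmf mass {total!r} deviates from 1 beyond tolerance {_MASS_TOL}"
        )
    return CountDistribution(probs=tuple(probs.tolist()), pmf=pmf / total)


def pmf_enumeration(probs: Sequence[float]) -> CountDistribution:
    """Subset-sum pmf: enumerate all 2^T subsets of the trials.

    The subsets, their probabilities and their sizes are materialised by
    array doubling over the trials; pmf[k] pools the probability of the
    size-k subsets.  Guarded at 20 trials (2^20 subsets).
    """
    p = _validate_probs(probs)
    t = p.size
    if t > ENUMERATION_MAX_TRIALS:
        raise ValueError(
            f"enumeration over 2^{t} subsets refused (cap {ENUMERATION_MAX_TRIALS} trials); "
            "use the convolution or DFT engine"
        )
    weight = np.array([1.0])
    size = np.zeros(1, dtype=np.int64)
    for pi in p:
        weight = np.concatenate([weight * (1.0 - pi), weight * pi])
        size = np.concatenate([size, size + 1])
    pmf = np.bincount(size, weights=weight, minlength=t + 1)
    return _finalize(p, pmf)


def pmf_convolution(probs: Sequence[float]) -> CountDistribution:
    """Exact iterative convolution of the per-trial (1 - p_i, p_i) laws."""
    p = _validate_probs(probs)
    pmf = np.array([1.0])
    for pi in p:
        nxt = np.zeros(pmf.size + 1)
        nxt[: pmf.size] += pmf * (1.0 - pi)
        nxt[1:] += pmf * pi
        pmf = nxt
    return _finalize(p, pmf)


def pmf_dft(probs: Sequence[float]) -> CountDistribution:
    """DFT closed-form pmf.

    The characteristic products z_l = prod_i (1 + (C^l - 1) p_i) are
    accumulated in complex double precision for each root of unity (O(T^2));
    the final sum over l for all k at once is the length-(T+1) DFT of z.
    """
    p = _validate_probs(probs)
    t = p.size
    if t == 0:
        return CountDistribution(probs=(), pmf=np.array([1.0]))
    ell = np.arange(t + 1)
    roots = np.exp(2j * np.pi * ell / (t + 1))  # C^l
    z = np.prod(1.0 + np.outer(roots - 1.0, p), axis=1)
    # pmf[k] = 1/(T+1) sum_l C^{-lk} z_l, i.e. the forward DFT of z
    pmf = np.fft.fft(z).real / (t + 1)
    return _finalize(p, pmf)
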