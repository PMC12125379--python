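"""Result containers shared by the computation methods."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any


@dataclass(frozen=True)
class ExpectedModularityResult:
    """Outcome of an expected-modularity computation.

    ``method`` names the algorithm (brute/pwp/fpwp/sample/threshold/weight);
    ``value`` is E(Q) (or its estimate); ``diagnostics`` carries
    method-specific bookkeeping such as per-community terms, the number of
    partition cells visited or worlds enumerated, sample counts, and elapsed
    wall time in seconds.
    """

    method: str
    value: float
    diagnostics: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class SamplingResult:
    """Monte Carlo estimate of expected modularity.

    ``estimate`` is the arithmetic mean of the per-sample modularity values;
    ``theta`` the number of sampled worlds; ``per_sample`` the retained
    Q_t values (None when not kept); ``seed`` the RNG seed; ``elapsed``
    wall-clock seconds.
    """

    estimate: float
    theta: int
    seed: int
    elapsed: float
    per_sample: tuple[float, ...] | None = None

    def to_result(self) -> ExpectedModularityResult:
        return ExpectedModularityResult(
            method="sample",
            value=self.estimate,
            diagnostics={"theta": self.theta, "seed": self.seed, "elapsed": self.elapsed},
        )
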