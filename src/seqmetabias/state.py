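"""Generating-model parameters shared across analytic and simulation modules."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["TrueState"]


@dataclass(frozen=True)
class TrueState:
    """True (generating) parameters for a first-stage effect estimate.

    The estimate is modelled as ``theta_hat ~ N(theta, sigma2/n1 + tau2)``:
    ``sigma2`` is the within-study population variance, ``n1`` the (effective)
    sample size and ``tau2`` the between-study heterogeneity variance of a
    random-effects model.  The sample variance ``s1^2`` is modelled as
    ``sigma2 * chi2(df) / df`` independent of the effect estimate.

    Scenarios that fix the total variance of the estimate directly (e.g. a
    per-estimate variance of 1/3) are expressed with ``n1 = 1``.
    """

    theta: float
    sigma2: float
    tau2: float = 0.0
    n1: float = 1.0
    df: int = 1

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be > 0")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not self.n1 > 0:
            raise ValueError("n1 must be > 0")
        if int(self.df) < 1:
            raise ValueError("df must be >= 1")

    @property
    def sampling_variance(self) -> float:
        """Marginal variance of the effect estimate, ``sigma2/n1 + tau2``."""
        return self.sigma2 / self.n1 + self.tau2

    @property
    def sampling_sd(self) -> float:
        return math.sqrt(self.sampling_variance)

    @property
    def weight(self) -> float:
        """Known-variance inverse-variance weight ``n1 / sigma2``."""
        return self.n1 / self.sigma2
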