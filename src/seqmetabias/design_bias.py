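"""Sequential design bias: sizing the next trial from the current estimate.

If the second trial's size is computed from the power formula with the
*estimated* effect ``theta_hat1 + delta`` in place of a fixed clinically
relevant effect, the pooled two-trial estimator is biased even though each
trial is individually unbiased.  With known first-stage weight
``w1 = n1/sigma1^2``, a variance guess ``sigma_g^2 = d^2 sigma2^2`` and
``n2 = max((c^2/(theta_hat1+delta)^2 - w1) * sigma_g^2, 0)``, the pooled
estimator is

    theta_hat_(2) = (w1 theta_hat1 + w2 theta_hat2) / (w1 + w2),
    w2 = n2 / sigma2^2,

which collapses to ``theta_hat1`` whenever the computed size is
non-positive (the sequence stops because the first trial already "had the
desired power" at its own estimate -- a strongly selective event).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .decision_models import PowerConstant, power_constant
from .state import TrueState

__all__ = [
    "DesignScenario",
    "combined_estimator_design",
    "stopped_expectation",
    "stopping_probability",
    "design_bias_upper_bound",
    "unconditional_design_expectation",
]


@dataclass(frozen=True)
class DesignScenario:
    """Configuration of a design-bias evaluation.

    ``true`` carries theta, the first trial's variance ``sigma2`` (=
    sigma1^2), size ``n1`` and the d.f. of its sample variance.  The
    variance guess used in the sizing formula is ``sigma2_guess``; setting
    ``use_s1_sq`` sizes with the first trial's *sample* variance instead.
    ``size_from`` selects the power target: the estimated effect
    ``theta_hat1 + delta`` ("estimate", the biased practice under study) or
    the true effect ("truth", the unbiased control).
    """

    true: TrueState
    sigma2_second: float
    sigma2_guess: float | None = None
    use_s1_sq: bool = False
    delta: float = 0.0
    alpha: float = 0.05
    beta: float = 0.2
    size_from: str = "estimate"
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma2_second > 0:
            raise ValueError("sigma2_second must be > 0")
        if self.use_s1_sq and self.sigma2_guess is not None:
            raise ValueError("give sigma2_guess or use_s1_sq, not both")
        if self.sigma2_guess is not None and not self.sigma2_guess > 0:
            raise ValueError("sigma2_guess must be > 0")
        if self.size_from not in ("estimate", "truth"):
            raise ValueError("size_from must be 'estimate' or 'truth'")

    @property
    def d_ratio(self) -> float:
        """Guessed-to-true SD ratio ``d = sigma_g / sigma_2`` (0 if unset)."""
        if self.sigma2_guess is None:
            return 0.0
        return math.sqrt(self.sigma2_guess / self.sigma2_second)

    @property
    def power(self) -> PowerConstant:
        return power_constant(self.alpha, self.beta)


def combined_estimator_design(
    theta1,
    theta2,
    w1: float,
    d_ratio: float,
    delta: float,
    c: PowerConstant,
):
    """Pooled estimate when the second trial is sized from ``theta1 + delta``.

    Internally ``w2 = max(c^2/(theta1+delta)^2 - w1, 0) * d^2``; when the
    computed size is non-positive (or d = 0) no second trial exists and the
    estimate is ``theta1`` itself.
    """
    if not w1 > 0:
        raise ValueError("w1 must be > 0")
    if d_ratio < 0:
        raise ValueError("d_ratio must be >= 0")
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    target2 = (t1 + delta) ** 2
    with np.errstate(divide="ignore"):
        w2 = np.where(target2 > 0.0, c.c2 / np.where(target2 > 0, target2, 1.0) - w1, np.inf)
    w2 = np.maximum(w2, 0.0) * d_ratio**2
    est = np.where(w2 > 0.0, (w1 * t1 + w2 * t2) / (w1 + w2), t1)
    return float(est) if np.isscalar(theta1) else est


def _stop_bounds(true: TrueState, delta: float, c: PowerConstant):
    """Stopping region |theta_hat1 + delta| >= c/sqrt(w1) as (lower, upper)."""
    half = c.c / math.sqrt(true.weight)
    return -half - delta, half - delta


def stopping_probability(true: TrueState, delta: float, c: PowerConstant) -> float:
    """P(n2 <= 0): the first estimate already meets its own power target."""
    lo, hi = _stop_bounds(true, delta, c)
    s = math.sqrt(true.sigma2 / true.n1)
    return float(
        stats.norm.cdf(lo, true.theta, s) + stats.norm.sf(hi, true.theta, s)
    )


def stopped_expectation(true: TrueState, delta: float, c: PowerConstant) -> float:
    """E[theta_hat1 | n2 <= 0] in closed form (two-sided truncated normal).

    The stopping event keeps both tails ``theta_hat1 <= -c/sqrt(w1) - delta``
    and ``theta_hat1 >= c/sqrt(w1) - delta``; in the scenarios of interest
    the upper tail dominates and the conditional mean overshoots theta.
    """
    lo, hi = _stop_bounds(true, delta, c)
    s = math.sqrt(true.sigma2 / true.n1)
    a_lo = (lo - true.theta) / s
    a_hi = (hi - true.theta) / s
    prob = stats.norm.cdf(a_lo) + stats.norm.sf(a_hi)
    if prob <= 0.0:
        raise ZeroDivisionError("stopping probability is 0; conditional undefined")
    partial = true.theta * prob + s * (stats.norm.pdf(a_hi) - stats.norm.pdf(a_lo))
    return float(partial / prob)


def design_bias_upper_bound(true: TrueState, delta: float, c: PowerConstant) -> float:
    """Upper bound on the design bias when the variance is guessed right (d=1).

    Returns ``phi(h) * sigma1/sqrt(n1) + 2 (theta + delta) / c^2`` with
    ``h = (c/sqrt(w1) - delta - theta) / (sigma1/sqrt(n1))``: the stopped
    branch contributes at most the truncated-normal term
    ``phi(h) sigma1/sqrt(n1)`` and the continuation branch at most
    ``2 (theta+delta)/c^2`` (a Stein-identity bound, since the estimator's
    effective shrinkage weight is capped at 1 on the continuation region).
    Relative to the sizing target theta + delta, the second term alone is
    ``2/c^2``, about 25% for the conventional alpha = 0.05, beta = 0.2.
    """
    s = math.sqrt(true.sigma2 / true.n1)
    h = (c.c / math.sqrt(true.weight) - delta - true.theta) / s
    return float(stats.norm.pdf(h) * s + 2.0 * (true.theta + delta) / c.c2)


def unconditional_design_expectation(scenario: DesignScenario) -> float:
    """E[theta_hat_(2)] under a design scenario.

    With a fixed variance guess the second trial contributes no bias and
    the expectation reduces to a one-dimensional quadrature over
    theta_hat1; with ``use_s1_sq`` (random guess) it is estimated by Monte
    Carlo through the simulation engine.
    """
    if scenario.use_s1_sq:
        from .mc_engine import simulate_design  # local import: engine depends on us

        table = simulate_design(scenario, variance_reduction=True)
        pct = float(table["percent_bias"].iloc[0])
        return scenario.true.theta * (1.0 + pct / 100.0)

    true = scenario.true
    c = scenario.power
    w1 = true.weight
    d2 = scenario.d_ratio**2
    delta = scenario.delta
    s = math.sqrt(true.sigma2 / true.n1)

    if scenario.size_from == "truth":
        # the target and hence both weights are non-random, and each stage
        # is unbiased: the pooled expectation is exactly theta
        return true.theta

    def integrand(t):
        n2 = (c.c2 / (t + delta) ** 2 - w1) * d2 if (t + delta) != 0 else math.inf
        if n2 <= 0.0:
            dev = t - true.theta
        else:
            dev = (
                w1
                * (t - true.theta)
                * (t + delta) ** 2
                / (w1 * (t + delta) ** 2 * (1.0 - d2) + d2 * c.c2)
            )
        return dev * stats.norm.pdf(t, true.theta, s)

    lo_b, hi_b = _stop_bounds(true, delta, c)
    lo, hi = true.theta - 10.0 * s, true.theta + 10.0 * s
    pts = sorted(p for p in (lo_b, hi_b, -delta) if lo < p < hi)
    bias, _ = integrate.quad(
        integrand, lo, hi, points=pts or None, epsabs=1e-10, epsrel=1e-10, limit=400
    )
    return float(true.theta + bias)
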