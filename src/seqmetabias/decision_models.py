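"""Models for the probability of conducting the next trial.

Three pointwise selection models map the current estimate ``theta_hat`` to a
probability of running another study:

* ``power_law``   -- p = (theta_hat/theta0)^t on (0, theta0), 0 elsewhere;
* ``extreme_value`` and ``probit`` -- Copas-style truncated selection
  functions p = [1 - G(theta_hat)] / [1 - G(r*theta0)] for
  theta_hat > r*theta0 and 0 otherwise, with G an extreme-value or probit
  distribution function centred at theta0.

The fourth model, ``power_calc_window``, runs the next trial when the
power-based required sample size ``n2 = c^2 s1^2 / theta_hat^2 - n1`` falls
in a window (a, b]; its continuation probabilities integrate over the
chi-square law of the sample variance and, unconditionally, the normal law
of the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate, stats

from .state import TrueState

__all__ = [
    "PowerConstant",
    "DecisionModel",
    "power_constant",
    "prob_power_law",
    "prob_truncated_selection",
    "sample_size_fixed_target",
    "sample_size_estimated_target",
    "continuation_prob_conditional",
    "continuation_prob_unconditional",
]

_VARIANTS = ("power_law", "extreme_value", "probit", "power_calc_window")


@dataclass(frozen=True)
class PowerConstant:
    """The sample-size constant ``c = z_{1-alpha/2} + z_{1-beta}``."""

    alpha: float
    beta: float
    c: float

    @property
    def c2(self) -> float:
        return self.c * self.c


def power_constant(alpha: float, beta: float) -> PowerConstant:
    """Two-quantile constant of the normal sample-size formula.

    ``alpha`` is the two-sided test size, ``beta`` the type-II error rate
    (power ``1 - beta``) at the target effect.
    """
    if not 0.0 < alpha < 1.0 or not 0.0 < beta < 1.0:
        raise ValueError("alpha and beta must lie in (0, 1)")
    c = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(1.0 - beta)
    return PowerConstant(alpha=alpha, beta=beta, c=float(c))


@dataclass(frozen=True)
class DecisionModel:
    """A rule for (the probability of) running the next trial.

    Only the fields relevant to ``variant`` are consulted.  For the window
    model, ``a`` is the strict lower and ``b`` the closed upper bound on the
    required size (ties at ``a`` stop, ties at ``b`` continue); ``a = None``
    removes the lower restriction altogether, so the rule is ``n2 <= b``.
    """

    variant: str
    theta0: float = 0.5
    t: float = 3.0                     # power-law exponent
    r: float = 0.8                     # truncation fraction of theta0
    alpha_sel: float = 0.0             # probit location
    beta_sel: float = 1.0              # probit slope
    sigma: float = 1.0                 # scale inside G
    a: float | None = None             # window lower bound on n2
    b: float = math.inf                # window upper bound on n2
    alpha: float = 0.05
    beta: float = 0.2
    delta: float = 0.0                 # offset added to theta_hat in sizing
    next_trial_size_policy: str = "fixed_b"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.next_trial_size_policy not in ("fixed_b", "computed_n2"):
            raise ValueError("next_trial_size_policy must be fixed_b or computed_n2")
        if self.a is not None and not self.a <= self.b:
            raise ValueError("window requires a <= b")

    # -- constructors ------------------------------------------------------
    @classmethod
    def power_law(cls, theta0: float, t: float = 3.0) -> "DecisionModel":
        return cls(variant="power_law", theta0=theta0, t=t)

    @classmethod
    def extreme_value(
        cls, theta0: float, r: float = 0.8, sigma: float = 1.0
    ) -> "DecisionModel":
        return cls(variant="extreme_value", theta0=theta0, r=r, sigma=sigma)

    @classmethod
    def probit(
        cls,
        theta0: float,
        r: float = 0.8,
        sigma: float = 1.0,
        alpha_sel: float = 0.0,
        beta_sel: float = 1.0,
    ) -> "DecisionModel":
        return cls(
            variant="probit",
            theta0=theta0,
            r=r,
            sigma=sigma,
            alpha_sel=alpha_sel,
            beta_sel=beta_sel,
        )

    @classmethod
    def power_window(
        cls,
        a: float | None,
        b: float,
        alpha: float = 0.05,
        beta: float = 0.2,
        delta: float = 0.0,
        next_trial_size_policy: str = "fixed_b",
    ) -> "DecisionModel":
        return cls(
            variant="power_calc_window",
            a=a,
            b=b,
            alpha=alpha,
            beta=beta,
            delta=delta,
            next_trial_size_policy=next_trial_size_policy,
        )

    def without_lower_bound(self) -> "DecisionModel":
        return replace(self, a=None)

    @property
    def power(self) -> PowerConstant:
        return power_constant(self.alpha, self.beta)

    # -- evaluation --------------------------------------------------------
    def prob(self, theta_hat, true: TrueState | None = None):
        """Probability of conducting the next trial at ``theta_hat``.

        For the window model this is the conditional continuation
        probability (the sample variance integrated out), which requires the
        generating state ``true``.
        """
        if self.variant == "power_law":
            return prob_power_law(theta_hat, self.theta0, self.t)
        if self.variant in ("extreme_value", "probit"):
            return prob_truncated_selection(theta_hat, self)
        if true is None:
            raise ValueError("power_calc_window probabilities need a TrueState")
        return continuation_prob_conditional(theta_hat, true, self)


def prob_power_law(theta_hat, theta0: float, t: float):
    """Power-law selection probability ``(theta_hat/theta0)^t`` on (0, theta0)."""
    if not theta0 > 0 or not t > 0:
        raise ValueError("theta0 and t must be > 0")
    x = np.asarray(theta_hat, dtype=float)
    p = np.where((x > 0) & (x < theta0), np.power(np.clip(x / theta0, 0, 1), t), 0.0)
    return float(p) if np.isscalar(theta_hat) else p


def _G(x, model: DecisionModel):
    """Selection distribution function of the truncated models."""
    if model.variant == "extreme_value":
        return np.exp(-np.exp((model.theta0 - x) / model.sigma))
    if model.variant == "probit":
        return stats.norm.cdf(
            model.alpha_sel + model.beta_sel * (x - model.theta0) / model.sigma
        )
    raise ValueError(f"no selection function for variant {model.variant!r}")


def prob_truncated_selection(theta_hat, model: DecisionModel):
    """Copas-style truncated selection probability.

    ``p = [1 - G(theta_hat)] / [1 - G(r*theta0)]`` for
    ``theta_hat > r*theta0`` and 0 at and below the truncation point; equals
    1 at the truncation point itself and decreases in ``theta_hat``.
    """
    if not 0.0 < model.r < 1.0:
        raise ValueError("r must lie in (0, 1)")
    if not model.sigma > 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(theta_hat, dtype=float)
    cut = model.r * model.theta0
    denom = 1.0 - _G(cut, model)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(x > cut, (1.0 - _G(x, model)) / denom, 0.0)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(theta_hat) else p


def sample_size_fixed_target(
    theta0: float, prior_weight: float, sigma_next2: float, c: PowerConstant
) -> float:
    """Required next-trial size ``(c^2/theta0^2 - W) * sigma_next2``.

    ``prior_weight`` is the accumulated inverse-variance weight ``W_i`` of
    the existing studies (0 for a stand-alone trial).  The result may be
    non-positive, meaning the existing evidence already achieves the target
    power; callers clamp with ``max(n, 0)``.
    """
    if theta0 == 0:
        raise ValueError("theta0 must be nonzero")
    if prior_weight < 0:
        raise ValueError("prior_weight must be >= 0")
    if not sigma_next2 > 0:
        raise ValueError("sigma_next2 must be > 0")
    return (c.c2 / theta0**2 - prior_weight) * sigma_next2


def sample_size_estimated_target(
    theta_hat1, s1_sq: float, n1: float, delta: float = 0.0, c: PowerConstant | None = None
):
    """Next-trial size with the *estimated* effect as the power target.

    ``n2 = c^2 s1^2 / (theta_hat1 + delta)^2 - n1``, using the first trial's
    sample variance as the guess for both variances.  A non-positive result
    means no further trial is conducted; a zero target (theta_hat1 + delta
    = 0) gives +inf, exceeding any finite window bound.
    """
    if not np.all(np.asarray(s1_sq) > 0):
        raise ValueError("s1_sq must be > 0")
    if not n1 > 0:
        raise ValueError("n1 must be > 0")
    if c is None:
        c = power_constant(0.05, 0.2)
    target = np.asarray(theta_hat1, dtype=float) + delta
    with np.errstate(divide="ignore"):
        n2 = np.where(target == 0.0, np.inf, c.c2 * s1_sq / np.where(target == 0.0, 1.0, target) ** 2 - n1)
    return float(n2) if np.isscalar(theta_hat1) and np.isscalar(s1_sq) else n2


def _chi2_window_args(theta1, true: TrueState, model: DecisionModel):
    """Chi-square CDF arguments of the window event a < n2 <= b.

    ``n2 = c^2 s1^2/theta1^2 - n1`` with ``df * s1^2/sigma1^2 ~ chi2(df)``,
    so ``a < n2 <= b`` is ``df (a+n1) theta1^2/(c^2 sigma1^2) < X <=
    df (b+n1) theta1^2 / (c^2 sigma1^2)``.  With no lower restriction the
    lower argument is 0 (the event is just ``n2 <= b``).
    """
    c2 = model.power.c2
    scale = true.df * np.asarray(theta1, dtype=float) ** 2 / (c2 * true.sigma2)
    hi = (model.b + true.n1) * scale if np.isfinite(model.b) else np.inf
    lo = (model.a + true.n1) * scale if model.a is not None else np.zeros_like(scale)
    return lo, hi


def continuation_prob_conditional(theta1, true: TrueState, model: DecisionModel):
    """P(a < n2 <= b | theta_hat1 = theta1) under the window rule.

    The sample variance is integrated out through its scaled chi-square law
    with ``true.df`` degrees of freedom.  At theta1 = 0 the required size
    diverges beyond any finite b, so the probability is 0.
    """
    if model.variant != "power_calc_window":
        raise ValueError("conditional continuation is defined for power_calc_window")
    lo, hi = _chi2_window_args(theta1, true, model)
    hi_cdf = stats.chi2.cdf(hi, true.df) if np.ndim(hi) or np.isfinite(hi) else 1.0
    p = np.asarray(hi_cdf - stats.chi2.cdf(lo, true.df))
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(theta1) else p


def continuation_prob_unconditional(true: TrueState, model: DecisionModel) -> float:
    """Marginal probability the window rule launches the next trial.

    Integrates the conditional probability against
    ``theta_hat1 ~ N(theta, sigma1^2/n1 + tau2)`` over theta +/- 10
    standard deviations (the omitted normal tail mass is < 1e-22).
    """
    sd = true.sampling_sd
    lo, hi = true.theta - 10.0 * sd, true.theta + 10.0 * sd

    def integrand(t):
        return continuation_prob_conditional(t, true, model) * stats.norm.pdf(
            t, true.theta, sd
        )

    points = [p for p in (0.0,) if lo < p < hi]
    value, err = integrate.quad(
        integrand, lo, hi, epsabs=1e-9, epsrel=1e-9, limit=300,
        points=points or None,
    )
    if err > 1e-6:
        raise RuntimeError(
            f"quadrature for the unconditional continuation probability did not "
            f"converge (estimated error {err:.2e})"
        )
    return float(min(max(value, 0.0), 1.0))
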