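"""Closed-form/quadrature evaluation of sequential decision bias.

When the probability ``p(theta_hat1)`` of conducting a second study depends
on the first estimate, the pooled two-study estimator is biased.  With
normalised first-study weight ``omega1`` and an unbiased first stage,

* unconditionally,        ``E[theta_hat_(2)] - theta = (omega1 - 1) * Cov(p, theta_hat1)``;
* given continuation,     ``bias = omega1 * Cov(p, theta_hat1) / E[p]``
  (plus ``omega1 * (E theta_hat1 - theta)``, retained so the expression
  composes into a recurrence over K sequential decisions);
* given stopping,         ``bias = -Cov(p, theta_hat1) / (1 - E[p])``.

All expectations are over ``theta_hat1 ~ N(theta, sigma2/n1 + tau2)``; for
the power-calculation window model, ``p`` is the conditional continuation
probability with the sample variance already integrated out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from scipy import integrate, stats

from .decision_models import DecisionModel
from .state import TrueState

__all__ = [
    "TrueState",
    "BiasDecomposition",
    "DecisionStep",
    "cov_p_theta",
    "mean_p",
    "unconditional_bias",
    "conditional_bias",
    "bias_decomposition",
    "recurrent_bias",
]

_QUAD_KW = dict(epsabs=1e-10, epsrel=1e-10, limit=300)


@dataclass(frozen=True)
class BiasDecomposition:
    """Unconditional and branch-conditional biases of the pooled estimator."""

    unconditional: float
    conditional_continue: float
    conditional_stop: float
    p_continue: float
    cov_p_theta: float


def _prob_fn(true: TrueState, model) -> Callable:
    if callable(model):
        return model

    def p(t):
        return model.prob(t, true)

    return p


def _breakpoints(true: TrueState, model, lo: float, hi: float):
    """Kinks of the decision probability, for the adaptive quadrature."""
    pts = [0.0]
    if isinstance(model, DecisionModel):
        if model.variant == "power_law":
            pts.append(model.theta0)
        elif model.variant in ("extreme_value", "probit"):
            pts.append(model.r * model.theta0)
    pts = sorted(p for p in pts if lo < p < hi)
    return pts or None


def _expect(true: TrueState, model: DecisionModel, weight: Callable) -> float:
    """E[weight(theta_hat1) * p(theta_hat1)] by adaptive quadrature."""
    sd = true.sampling_sd
    lo, hi = true.theta - 10.0 * sd, true.theta + 10.0 * sd
    p = _prob_fn(true, model)

    def integrand(t):
        return weight(t) * p(t) * stats.norm.pdf(t, true.theta, sd)

    value, _ = integrate.quad(
        integrand, lo, hi, points=_breakpoints(true, model, lo, hi), **_QUAD_KW
    )
    return float(value)


def mean_p(true: TrueState, model: DecisionModel) -> float:
    """E[p(theta_hat1)], the marginal continuation probability."""
    return min(max(_expect(true, model, lambda t: 1.0), 0.0), 1.0)


def cov_p_theta(true: TrueState, model) -> float:
    """Cov(p(theta_hat1), theta_hat1) under the generating normal law.

    ``model`` is a :class:`DecisionModel` or any callable ``p(theta_hat)``
    returning a probability (vectorisation not required).
    """
    ep = _expect(true, model, lambda t: 1.0)
    ept = _expect(true, model, lambda t: t)
    return ept - ep * true.theta


def unconditional_bias(true: TrueState, model: DecisionModel, omega1: float) -> float:
    """Unconditional bias ``(omega1 - 1) * Cov(p, theta_hat1)``.

    A positive covariance (promising results encourage the next trial)
    makes the pooled estimator negatively biased.
    """
    _check_omega(omega1)
    return (omega1 - 1.0) * cov_p_theta(true, model)


def conditional_bias(
    true: TrueState, model: DecisionModel, omega1: float, branch: str = "continue"
) -> float:
    """Bias of the pooled estimator given the decision branch.

    ``continue``: ``omega1 * Cov(p, theta_hat1)/E[p]`` (the first stage is
    unbiased here, so the carried ``omega1*(E theta_hat1 - theta)`` term is
    zero); ``stop``: ``-Cov(p, theta_hat1) / (1 - E[p])``.
    """
    _check_omega(omega1)
    ep = mean_p(true, model)
    cov = cov_p_theta(true, model)
    if branch == "continue":
        if ep <= 0.0:
            raise ZeroDivisionError("continuation has probability 0; branch undefined")
        return omega1 * cov / ep
    if branch == "stop":
        if ep >= 1.0:
            raise ZeroDivisionError("stopping has probability 0; branch undefined")
        return -cov / (1.0 - ep)
    raise ValueError("branch must be 'continue' or 'stop'")


def bias_decomposition(
    true: TrueState, model: DecisionModel, omega1: float
) -> BiasDecomposition:
    """All three biases plus the continuation probability and covariance.

    Satisfies the total-expectation identity
    ``p * bias_continue + (1 - p) * bias_stop = unconditional bias``.
    """
    _check_omega(omega1)
    ep = mean_p(true, model)
    cov = cov_p_theta(true, model)
    uncond = (omega1 - 1.0) * cov
    cont = omega1 * cov / ep if ep > 0.0 else float("nan")
    stop = -cov / (1.0 - ep) if ep < 1.0 else float("nan")
    return BiasDecomposition(
        unconditional=uncond,
        conditional_continue=cont,
        conditional_stop=stop,
        p_continue=ep,
        cov_p_theta=cov,
    )


@dataclass(frozen=True)
class DecisionStep:
    """One step of the K-trial recurrence.

    ``cov`` is Cov(p_i, theta_hat_(i)) between the cumulative estimate and
    the probability of running trial i+1; ``mean_p`` is E[p_i]; and
    ``omega_bar`` is the relative weight of the first i studies in the
    (i+1)-study pool, ``(sum_1..i w_j) / (sum_1..i+1 w_j)``.
    """

    cov: float
    mean_p: float
    omega_bar: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_p <= 1.0:
            raise ValueError("mean_p must lie in (0, 1]")
        if not 0.0 < self.omega_bar <= 1.0:
            raise ValueError("omega_bar must lie in (0, 1]")


def recurrent_bias(steps: Sequence[DecisionStep], initial_bias: float = 0.0) -> float:
    """Conditional bias of the K-study pooled estimate, all trials run.

    Applies ``bias_{i+1} = omega_bar_i * (bias_i + cov_i / E[p_i])`` from
    the first decision onward; with one step and an unbiased start this is
    the two-trial continue-branch expression.
    """
    if not steps:
        raise ValueError("at least one decision step is required")
    bias = initial_bias
    for step in steps:
        bias = step.omega_bar * (bias + step.cov / step.mean_p)
    return bias


def _check_omega(omega1: float) -> None:
    if not 0.0 < omega1 <= 1.0:
        raise ValueError("omega1 must lie in (0, 1]")
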