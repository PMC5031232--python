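"""Seeded Monte-Carlo engine for sequential decision and design bias.

The engine draws first-stage summaries from the generating model
(``theta_hat ~ N(theta, sigma2/n + tau2)``, ``s^2 ~ sigma2 chi2(df)/df``),
applies a decision rule per replicate -- Bernoulli with probability
``p(theta_hat)`` for the selection models, the deterministic sample-size
window for the power-calculation model -- pools continuing replicates, and
reports unconditional and branch-conditional biases with their Monte-Carlo
standard errors.  It doubles as the simulation oracle for the quadrature
modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import design_bias as _db
from .decision_models import DecisionModel, sample_size_estimated_target
from .state import TrueState

__all__ = [
    "SimConfig",
    "BiasResult",
    "draw_study",
    "simulate_decision",
    "simulate_design",
    "grid_sweep",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a decision-bias simulation.

    ``steps`` is the number of studies in the longest sequence (2 = one
    decision).  ``weights_policy`` is ``equal`` (the paper's heatmap/grid
    scenarios) or ``inverse_variance`` (known-variance weights n_i/sigma^2).
    ``grid`` optionally maps any of ``theta``, ``theta0``, ``tau2`` to value
    lists for :func:`grid_sweep`.
    """

    true: TrueState
    model: DecisionModel
    weights_policy: str = "equal"
    steps: int = 2
    reps: int = 10_000
    seed: int = 0
    grid: dict | None = None

    def __post_init__(self) -> None:
        if self.weights_policy not in ("equal", "inverse_variance"):
            raise ValueError("weights_policy must be 'equal' or 'inverse_variance'")
        if self.steps < 2:
            raise ValueError("steps must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.model.variant == "power_calc_window" and self.steps != 2:
            raise NotImplementedError(
                "the power-calculation window rule is implemented for a single "
                "decision (steps = 2)"
            )


@dataclass(frozen=True)
class BiasResult:
    """Bias estimates from one simulation run (effect-scale units).

    ``conditional_bias_continue`` refers to replicates that conducted every
    trial; an empty branch is reported as NaN, never as zero.  ``percent``
    re-expresses the biases as 100 * bias / theta.
    """

    theta: float
    unconditional_bias: float
    conditional_bias_continue: float
    conditional_bias_stop: float
    p_continue: float
    mc_se: dict = field(default_factory=dict)
    n_continue: int = 0
    n_stop: int = 0
    reps_used: int = 0
    seed: int = 0

    @property
    def percent(self) -> dict:
        f = 100.0 / self.theta
        return {
            "unconditional": self.unconditional_bias * f,
            "continue": self.conditional_bias_continue * f,
            "stop": self.conditional_bias_stop * f,
        }


def draw_study(true: TrueState, rng: np.random.Generator, size: int | None = None):
    """Draw (theta_hat, s2) pairs from the generating model."""
    theta_hat = rng.normal(true.theta, true.sampling_sd, size)
    s2 = true.sigma2 * rng.chisquare(true.df, size) / true.df
    return theta_hat, s2


def _branch_stats(values: np.ndarray, theta: float):
    if values.size == 0:
        return float("nan"), float("nan")
    se = values.std(ddof=1) / math.sqrt(values.size) if values.size > 1 else float("nan")
    return float(values.mean() - theta), float(se)


def simulate_decision(config: SimConfig, variance_reduction: bool = False) -> BiasResult:
    """Simulate sequential decisions and pool the continuing replicates.

    Replicates that stop keep their cumulative estimate frozen at the stop
    step; the continue branch holds the replicates that conducted all
    ``steps`` trials.  Reruns with the same config and seed are
    bit-identical.

    With ``variance_reduction`` (single-decision scenarios only) the same
    estimands are computed by conditional Monte Carlo: first-stage draws
    are stratified through the inverse normal CDF, the decision indicator
    is replaced by its conditional probability given the estimate (the
    sample variance integrated out through its chi-square law for the
    window rule), and the second trial is integrated out analytically.
    Branch means are then probability-weighted averages; reported
    standard errors use the iid formula and are conservative.
    """
    if variance_reduction:
        if config.steps != 2:
            raise NotImplementedError("variance reduction covers a single decision")
        return _simulate_decision_vr(config)
    rng = np.random.default_rng(config.seed)
    true, model, reps = config.true, config.model, config.reps
    th1, s1 = draw_study(true, rng, reps)

    cum_est = th1.copy()
    cum_w = np.full(reps, true.weight)  # inverse-variance running weight
    cum_n = np.full(reps, float(true.n1))
    active = np.ones(reps, dtype=bool)

    for step in range(2, config.steps + 1):
        if model.variant == "power_calc_window":
            n_req = sample_size_estimated_target(
                cum_est, s1, true.n1, delta=model.delta, c=model.power
            )
            go = n_req <= model.b
            if model.a is not None:
                go &= n_req > model.a
            if model.next_trial_size_policy == "fixed_b":
                n_next = np.full(reps, float(model.b))
            else:
                n_next = np.clip(np.where(np.isfinite(n_req), n_req, 1.0), 1.0, None)
        else:
            p = model.prob(cum_est)
            go = rng.random(reps) < p
            n_next = np.full(reps, float(true.n1))

        active &= go
        var_next = true.sigma2 / n_next + true.tau2
        th_next = rng.normal(true.theta, np.sqrt(var_next), reps)

        if config.weights_policy == "equal":
            updated = ((step - 1) * cum_est + th_next) / step
        else:
            w_next = n_next / true.sigma2
            updated = (cum_w * cum_est + w_next * th_next) / (cum_w + w_next)
            cum_w = np.where(active, cum_w + w_next, cum_w)
        cum_est = np.where(active, updated, cum_est)
        cum_n = np.where(active, cum_n + n_next, cum_n)

    uncond_bias, uncond_se = _branch_stats(cum_est, true.theta)
    cont_bias, cont_se = _branch_stats(cum_est[active], true.theta)
    stop_bias, stop_se = _branch_stats(cum_est[~active], true.theta)
    p_cont = float(active.mean())
    return BiasResult(
        theta=true.theta,
        unconditional_bias=uncond_bias,
        conditional_bias_continue=cont_bias,
        conditional_bias_stop=stop_bias,
        p_continue=p_cont,
        mc_se={
            "unconditional": uncond_se,
            "continue": cont_se,
            "stop": stop_se,
            "p_continue": math.sqrt(max(p_cont * (1 - p_cont), 0.0) / reps),
        },
        n_continue=int(active.sum()),
        n_stop=int(reps - active.sum()),
        reps_used=reps,
        seed=config.seed,
    )


def _simulate_decision_vr(config: SimConfig) -> BiasResult:
    """Conditional-Monte-Carlo variant of a single-decision simulation."""
    from scipy import stats

    from .decision_models import continuation_prob_conditional

    rng = np.random.default_rng(config.seed)
    true, model, reps = config.true, config.model, config.reps

    u = (np.arange(reps) + rng.random(reps)) / reps
    th1 = true.theta + true.sampling_sd * stats.norm.ppf(u)

    if model.variant == "power_calc_window":
        p = continuation_prob_conditional(th1, true, model)
        if model.next_trial_size_policy == "fixed_b":
            n_next = np.full(reps, float(model.b))
        else:
            # conditional expected size has no simple closed form; use the
            # size implied by the true variance as the pooled weight
            n_next = np.clip(
                sample_size_estimated_target(th1, true.sigma2, true.n1,
                                             model.delta, model.power),
                1.0, None,
            )
    else:
        p = np.asarray(model.prob(th1), dtype=float)
        n_next = np.full(reps, float(true.n1))

    if config.weights_policy == "equal":
        est_cont = 0.5 * (th1 + true.theta)  # E[theta_hat2] = theta
    else:
        w1 = true.weight
        w2 = n_next / true.sigma2
        est_cont = (w1 * th1 + w2 * true.theta) / (w1 + w2)

    p_cont = float(p.mean())
    mass_cont = p.sum()
    mass_stop = (1.0 - p).sum()
    cont_mean = float((p * est_cont).sum() / mass_cont) if mass_cont > 0 else float("nan")
    stop_mean = float(((1 - p) * th1).sum() / mass_stop) if mass_stop > 0 else float("nan")
    uncond_mean = float((p * est_cont + (1 - p) * th1).mean())

    def _wse(values, weights, mean):
        total = weights.sum()
        if total <= 0:
            return float("nan")
        var = float((weights * (values - mean) ** 2).sum() / total)
        return math.sqrt(var / total)

    return BiasResult(
        theta=true.theta,
        unconditional_bias=uncond_mean - true.theta,
        conditional_bias_continue=cont_mean - true.theta,
        conditional_bias_stop=stop_mean - true.theta,
        p_continue=p_cont,
        mc_se={
            "unconditional": float(
                (p * est_cont + (1 - p) * th1).std(ddof=1) / math.sqrt(reps)
            ),
            "continue": _wse(est_cont, p, cont_mean),
            "stop": _wse(th1, 1.0 - p, stop_mean),
            "p_continue": float(p.std(ddof=1) / math.sqrt(reps)),
        },
        n_continue=int(round(mass_cont)),
        n_stop=int(round(mass_stop)),
        reps_used=reps,
        seed=config.seed,
    )


def _design_run(
    scenario: _db.DesignScenario,
    sigma2_guess: float | None,
    rng: np.random.Generator,
    variance_reduction: bool,
):
    """One design simulation; returns (mean percent bias, MC standard error).

    With ``variance_reduction`` the second trial is integrated out
    analytically (its conditional mean is theta), first-stage draws are
    antithetic, and regression control variates on theta_hat1 and s1^2
    (whose means are known) are removed; the estimand is unchanged.
    """
    true = scenario.true
    c = scenario.power
    w1 = true.weight
    reps = scenario.reps
    sd1 = math.sqrt(true.sigma2 / true.n1)

    if variance_reduction:
        half = rng.standard_normal(reps // 2)
        z = np.concatenate([half, -half])
        reps = z.size
    else:
        z = rng.standard_normal(reps)
    th1 = true.theta + sd1 * z
    s1sq = true.sigma2 * rng.chisquare(true.df, reps) / true.df
    guess = s1sq if scenario.use_s1_sq else np.full(reps, float(sigma2_guess))

    if scenario.size_from == "truth":
        target = np.full(reps, true.theta)
    else:
        target = th1 + scenario.delta
    with np.errstate(divide="ignore"):
        n2 = np.where(target == 0.0, np.inf, (c.c2 / target**2 - w1)) * guess
    n2 = np.maximum(n2, 0.0)
    go = n2 > 0
    w2 = n2 / scenario.sigma2_second

    if variance_reduction:
        comb = (w1 * th1 + w2 * true.theta) / (w1 + w2)
    else:
        scale = np.sqrt(scenario.sigma2_second / np.maximum(n2, 1e-300))
        th2 = np.where(go, true.theta + scale * rng.standard_normal(reps), 0.0)
        comb = np.where(go, (w1 * th1 + w2 * th2) / (w1 + w2), th1)

    y = 100.0 * (comb - true.theta) / true.theta
    if variance_reduction:
        controls = np.column_stack([th1 - true.theta, s1sq - true.sigma2])
        centred = controls - controls.mean(axis=0)
        beta = np.linalg.lstsq(centred, y - y.mean(), rcond=None)[0]
        y = y - controls @ beta
        m = reps // 2
        pair_means = 0.5 * (y[:m] + y[m:])
        se = pair_means.std(ddof=1) / math.sqrt(m)
    else:
        se = y.std(ddof=1) / math.sqrt(reps)
    return float(y.mean()), float(se)


def simulate_design(
    scenario: _db.DesignScenario,
    d_grid=None,
    variance_reduction: bool = False,
) -> pd.DataFrame:
    """Mean percent bias of the design-sized pooled estimator.

    With ``d_grid`` the variance guess is swept as ``sigma_g^2 = d^2 *
    sigma2_second^2`` (one independent substream per d); otherwise the
    scenario's own guess (``sigma2_guess`` or the sample variance when
    ``use_s1_sq``) is used once.  Returns a table with columns
    ``d, percent_bias, se``.
    """
    rows = []
    if d_grid is None:
        rng = np.random.default_rng(scenario.seed)
        guess = None if scenario.use_s1_sq else scenario.sigma2_guess
        if guess is None and not scenario.use_s1_sq:
            raise ValueError("scenario has no variance guess and use_s1_sq is False")
        mean, se = _design_run(scenario, guess, rng, variance_reduction)
        rows.append(
            {
                "d": scenario.d_ratio if not scenario.use_s1_sq else float("nan"),
                "percent_bias": mean,
                "se": se,
            }
        )
    else:
        d_grid = np.asarray(d_grid, dtype=float)
        streams = np.random.SeedSequence(scenario.seed).spawn(d_grid.size)
        for d, ss in zip(d_grid, streams):
            rng = np.random.default_rng(ss)
            guess = d * d * scenario.sigma2_second
            mean, se = _design_run(
                replace(scenario, use_s1_sq=False, sigma2_guess=None),
                guess,
                rng,
                variance_reduction,
            )
            rows.append({"d": float(d), "percent_bias": mean, "se": se})
    return pd.DataFrame(rows)


def grid_sweep(config: SimConfig) -> pd.DataFrame:
    """Run :func:`simulate_decision` over a (theta, theta0, tau2) grid.

    Emits a long-format table with columns ``theta, theta0, tau2,
    estimand, value`` covering the continuation probability and the three
    bias estimands; each grid point runs on its own deterministic
    substream, so any point can be reproduced in isolation.
    """
    if not config.grid:
        raise ValueError("config.grid must supply value lists")
    thetas = np.atleast_1d(config.grid.get("theta", [config.true.theta]))
    theta0s = np.atleast_1d(config.grid.get("theta0", [config.model.theta0]))
    tau2s = np.atleast_1d(config.grid.get("tau2", [config.true.tau2]))

    points = [(t, t0, tau2) for tau2 in tau2s for t0 in theta0s for t in thetas]
    streams = np.random.SeedSequence(config.seed).spawn(len(points))
    rows = []
    for (theta, theta0, tau2), ss in zip(points, streams):
        sub = replace(
            config,
            true=replace(config.true, theta=float(theta), tau2=float(tau2)),
            model=replace(config.model, theta0=float(theta0)),
            seed=int(ss.generate_state(1)[0] % (2**31)),
            grid=None,
        )
        res = simulate_decision(sub)
        for name, value in (
            ("p_continue", res.p_continue),
            ("unconditional_bias", res.unconditional_bias),
            ("conditional_bias_continue", res.conditional_bias_continue),
            ("conditional_bias_stop", res.conditional_bias_stop),
        ):
            rows.append(
                {
                    "theta": float(theta),
                    "theta0": float(theta0),
                    "tau2": float(tau2),
                    "estimand": name,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)
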