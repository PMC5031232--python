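import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from seqmetabias import (
    DecisionModel,
    TrueState,
    continuation_prob_conditional,
    continuation_prob_unconditional,
    power_constant,
    prob_power_law,
    prob_truncated_selection,
    sample_size_estimated_target,
    sample_size_fixed_target,
)


class TestPowerConstant:
    def test_conventional_value(self):
        c = power_constant(0.05, 0.2)
        assert c.c == pytest.approx(2.802, abs=5e-4)
        assert c.c2 == pytest.approx(7.85, abs=5e-3)

    def test_half_power_reduces_to_single_quantile(self):
        c = power_constant(0.05, 0.5)
        assert c.c == pytest.approx(stats.norm.ppf(0.975))

    @pytest.mark.parametrize("alpha, beta", [(0.0, 0.2), (0.05, 1.0), (-0.1, 0.2)])
    def test_out_of_range(self, alpha, beta):
        with pytest.raises(ValueError):
            power_constant(alpha, beta)


class TestPowerLaw:
    @pytest.mark.parametrize(
        "theta_hat, theta0, t, expected",
        [
            (0.25, 0.5, 1.0, 0.5),     # uniform case
            (0.25, 0.5, 3.0, 0.125),   # cube
            (0.6, 0.5, 3.0, 0.0),      # effect already at the target
            (-0.1, 0.5, 3.0, 0.0),
            (0.5, 0.5, 3.0, 0.0),
        ],
    )
    def test_values(self, theta_hat, theta0, t, expected):
        assert prob_power_law(theta_hat, theta0, t) == pytest.approx(expected)

    def test_monotone_nondecreasing_below_target(self):
        xs = np.linspace(1e-6, 0.5 - 1e-6, 200)
        ps = prob_power_law(xs, 0.5, 3.0)
        assert np.all(np.diff(ps) >= 0)
        assert np.all((ps >= 0) & (ps <= 1))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            prob_power_law(0.2, -0.5, 3.0)
        with pytest.raises(ValueError):
            prob_power_law(0.2, 0.5, 0.0)


class TestTruncatedSelection:
    @pytest.fixture(params=["extreme_value", "probit"])
    def model(self, request):
        if request.param == "extreme_value":
            return DecisionModel.extreme_value(theta0=0.5, r=0.8, sigma=0.6)
        return DecisionModel.probit(theta0=0.5, r=0.8, sigma=0.6, alpha_sel=0.1,
                                    beta_sel=1.3)

    def test_one_at_truncation_point_zero_below(self, model):
        cut = model.r * model.theta0
        assert prob_truncated_selection(cut + 1e-12, model) == pytest.approx(1.0)
        assert prob_truncated_selection(cut, model) == 0.0
        assert prob_truncated_selection(cut - 0.2, model) == 0.0

    def test_grid_against_direct_selection_function(self, model):
        """Match brute-force evaluation of [1-G(x)]/[1-G(r theta0)]."""
        xs = np.linspace(0.41, 3.0, 150)
        if model.variant == "extreme_value":
            G = lambda x: np.exp(-np.exp((model.theta0 - x) / model.sigma))
        else:
            G = lambda x: stats.norm.cdf(
                model.alpha_sel + model.beta_sel * (x - model.theta0) / model.sigma
            )
        expected = (1 - G(xs)) / (1 - G(model.r * model.theta0))
        got = prob_truncated_selection(xs, model)
        assert got == pytest.approx(np.clip(expected, 0, 1), rel=1e-10)
        assert np.all(np.diff(got) <= 1e-12)  # non-increasing above the cut

    def test_vanishes_for_large_effects(self, model):
        assert prob_truncated_selection(50.0, model) == pytest.approx(0.0, abs=1e-12)


class TestSampleSizeFixedTarget:
    def test_boundary_zero(self, c_standard):
        prior = c_standard.c2 / 0.5**2
        assert sample_size_fixed_target(0.5, prior, 2.0, c_standard) == pytest.approx(0.0)

    def test_linear_in_variance(self, c_standard):
        n1 = sample_size_fixed_target(0.5, 1.0, 2.0, c_standard)
        n2 = sample_size_fixed_target(0.5, 1.0, 4.0, c_standard)
        assert n2 == pytest.approx(2 * n1)

    @pytest.mark.parametrize("prior_weight", [0.0, 5.0, 20.0])
    def test_wald_power_at_returned_size(self, c_standard, prior_weight):
        """The returned size gives the two-sided Wald test ~80% power.

        Brute-force power: the pooled estimate has variance 1/(W + n/s2),
        so at the target effect the rejection probability of the level-alpha
        z-test must equal 1 - beta (up to the negligible opposite tail).
        """
        theta0, sigma2 = 0.4, 3.0
        n = sample_size_fixed_target(theta0, prior_weight, sigma2, c_standard)
        total_w = prior_weight + n / sigma2
        z = stats.norm.ppf(0.975)
        mean = theta0 * np.sqrt(total_w)
        power = stats.norm.sf(z - mean) + stats.norm.cdf(-z - mean)
        assert power == pytest.approx(0.8, abs=1e-6)

    def test_zero_target_rejected(self, c_standard):
        with pytest.raises(ValueError):
            sample_size_fixed_target(0.0, 1.0, 2.0, c_standard)


class TestSampleSizeEstimatedTarget:
    def test_johnson_first_trial(self, c_standard):
        n2 = sample_size_estimated_target(0.86, 19.94, 61.30, 0.0, c_standard)
        assert n2 == pytest.approx(150.35, abs=0.05)

    def test_large_estimate_stops(self, c_standard):
        assert sample_size_estimated_target(100.0, 19.94, 61.30, 0.0, c_standard) < 0

    def test_scale_invariance_up_to_prior_term(self, c_standard):
        base = sample_size_estimated_target(0.5, 4.0, 10.0, 0.0, c_standard)
        scaled = sample_size_estimated_target(1.0, 16.0, 10.0, 0.0, c_standard)
        assert scaled == pytest.approx(base)

    def test_zero_target_is_unbounded(self, c_standard):
        assert sample_size_estimated_target(0.3, 4.0, 10.0, -0.3, c_standard) == np.inf


class TestContinuationProbability:
    state = TrueState(theta=0.3, sigma2=20.0, n1=60.0, df=59)
    model = DecisionModel.power_window(a=30.0, b=80.0)

    def test_zero_estimate_never_continues(self):
        assert continuation_prob_conditional(0.0, self.state, self.model) == 0.0

    @pytest.mark.parametrize("theta1", [1.05, 1.15, 1.30])
    def test_conditional_against_chi_square_monte_carlo(self, theta1):
        """Generic points vs a 1e6-draw chi-square simulation (3 SE)."""
        rng = np.random.default_rng(2024)
        s1 = self.state.sigma2 * rng.chisquare(self.state.df, 1_000_000) / self.state.df
        c2 = self.model.power.c2
        n2 = c2 * s1 / theta1**2 - self.state.n1
        hits = (n2 > self.model.a) & (n2 <= self.model.b)
        p_mc = hits.mean()
        se = np.sqrt(p_mc * (1 - p_mc) / hits.size)
        assert 0.05 < p_mc < 0.95  # an informative point, not a tail case
        p = continuation_prob_conditional(theta1, self.state, self.model)
        assert abs(p - p_mc) < 3 * se

    def test_conditional_negligible_for_small_estimates(self):
        """A small estimate demands a huge trial: the window never catches it."""
        assert continuation_prob_conditional(0.3, self.state, self.model) < 1e-12

    def test_degenerate_df_limit_is_indicator(self):
        """As df -> inf the rule becomes deterministic in theta1."""
        state = TrueState(theta=0.3, sigma2=20.0, n1=60.0, df=10**6)
        c2 = self.model.power.c2
        for theta1 in (0.2, 0.5, 1.0, 1.4):
            n2 = c2 * state.sigma2 / theta1**2 - state.n1
            ind = float(self.model.a < n2 <= self.model.b)
            p = continuation_prob_conditional(theta1, state, self.model)
            assert p == pytest.approx(ind, abs=1e-2)

    def test_zero_width_window(self):
        model = DecisionModel.power_window(a=80.0, b=80.0)
        assert continuation_prob_unconditional(self.state, model) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_unconditional_matches_monte_carlo(self):
        """Quadrature equals the simulated window fraction within 3 SE."""
        rng = np.random.default_rng(7)
        reps = 100_000
        th1 = rng.normal(self.state.theta, self.state.sampling_sd, reps)
        s1 = self.state.sigma2 * rng.chisquare(self.state.df, reps) / self.state.df
        c2 = self.model.power.c2
        with np.errstate(divide="ignore"):
            n2 = np.where(th1 == 0, np.inf, c2 * s1 / th1**2 - self.state.n1)
        p_mc = ((n2 > self.model.a) & (n2 <= self.model.b)).mean()
        se = np.sqrt(p_mc * (1 - p_mc) / reps)
        p = continuation_prob_unconditional(self.state, self.model)
        assert abs(p - p_mc) < 3 * se

    def test_no_lower_bound_dominates_windowed(self):
        free = self.model.without_lower_bound()
        p_free = continuation_prob_unconditional(self.state, free)
        p_win = continuation_prob_unconditional(self.state, self.model)
        assert p_free >= p_win


@given(
    theta_hat=st.floats(-3, 3),
    theta0=st.floats(0.05, 2.0),
    t=st.floats(0.1, 6.0),
    r=st.floats(0.05, 0.95),
    sigma=st.floats(0.05, 3.0),
)
@settings(max_examples=200, deadline=None)
def test_all_probabilities_in_unit_interval(theta_hat, theta0, t, r, sigma):
    assert 0.0 <= prob_power_law(theta_hat, theta0, t) <= 1.0
    for ctor in (DecisionModel.extreme_value, DecisionModel.probit):
        m = ctor(theta0=theta0, r=r, sigma=sigma)
        assert 0.0 <= prob_truncated_selection(theta_hat, m) <= 1.0
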