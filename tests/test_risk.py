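import numpy as np
import pytest
from scipy.stats import chi2

from modesign import (
    OutcomeModel,
    RiskParams,
    conditional_mse,
    cre_assign,
    difference_in_means,
    enumerate_assignment_moments,
    max_risk,
    max_risk_split_form,
    mode_assign,
    outcome_model,
    percent_reduction,
    randomization_variance,
    true_ate,
    va_factor,
)


def _constant_model(c1=0.0, c0=0.0, s1=0.0, s0=0.0):
    return OutcomeModel(
        f1=lambda X: np.full(X.shape[0], c1),
        f0=lambda X: np.full(X.shape[0], c0),
        s1sq=lambda X: np.full(X.shape[0], s1),
        s0sq=lambda X: np.full(X.shape[0], s0),
    )


def _table_model(f1_vals, f0_vals, s1=0.0, s0=0.0):
    """Unit-indexed potential outcome means keyed on the first covariate."""
    f1_vals = np.asarray(f1_vals, float)
    f0_vals = np.asarray(f0_vals, float)
    return OutcomeModel(
        f1=lambda X: f1_vals[X[:, 0].astype(int)],
        f0=lambda X: f0_vals[X[:, 0].astype(int)],
        s1sq=lambda X: np.full(X.shape[0], s1),
        s0sq=lambda X: np.full(X.shape[0], s0),
    )


def _index_X(n):
    return np.arange(n, dtype=float).reshape(-1, 1)


class TestDifferenceInMeans:
    @pytest.mark.parametrize(
        "T, Y, expected",
        [
            ([1, 0], [5, 3], 2.0),
            ([1, 0, 1, 0], [4, 4, 4, 4], 0.0),
            ([1, 1, 0, 0], [4, 6, 1, 3], 3.0),
        ],
    )
    def test_examples(self, T, Y, expected):
        assert difference_in_means(T, Y) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            difference_in_means([1, 0, 1], [1.0, 2.0])


class TestTrueATE:
    def test_additive_effect(self, rng):
        X = rng.normal(size=(20, 2))
        assert true_ate(X, _constant_model(c1=3.5, c0=1.5)) == pytest.approx(2.0)

    def test_no_effect(self, rng):
        X = rng.normal(size=(10, 3))
        assert true_ate(X, _constant_model(c1=1.0, c0=1.0)) == 0.0

    def test_c3_hand_example(self):
        # rows with x~ = 0 and x~ = 2: tau = (2*1 + 2*e) / 2
        X = np.array([[0.0], [2.0]])
        assert true_ate(X, outcome_model("C3")) == pytest.approx(
            (2.0 + 2.0 * np.e) / 2.0)


class TestConditionalMSE:
    def test_variance_collapses_for_constant_sigma(self):
        X = _index_X(6)
        model = _constant_model(s1=2.0, s0=2.0)
        V, B = conditional_mse([1, 1, 0, 0, 0, 1], X, model)
        assert V == pytest.approx(2.0 * (1 / 3 + 1 / 3))
        assert B == pytest.approx(0.0)

    def test_no_bias_for_constant_means(self):
        X = _index_X(8)
        _, B = conditional_mse(cre_assign(8, seed=0), X, _constant_model(c1=5, c0=5))
        assert B == pytest.approx(0.0)

    def test_hand_computed_bias(self):
        model = _table_model([1, 2, 3, 4], [0, 0, 0, 0])
        X = _index_X(4)
        _, b_balanced = conditional_mse([1, 0, 0, 1], X, model)
        assert b_balanced == pytest.approx(0.0)  # (2.5 - 0 - 2.5)^2
        _, b_skewed = conditional_mse([1, 1, 0, 0], X, model)
        assert b_skewed == pytest.approx(1.0)  # (1.5 - 0 - 2.5)^2


class TestMaxRisk:
    def test_zero_gamma_leaves_only_variance(self, rng):
        X = rng.normal(size=(10, 2))
        rep = max_risk(cre_assign(10, seed=0), X, RiskParams(sigma2=2.0, gamma2=0.0))
        assert rep.total == pytest.approx(2.0 * (1 / 5 + 1 / 5))

    def test_two_point_bias_only(self):
        X = np.array([[0.0], [1.0]])
        rep = max_risk([1, 0], X, RiskParams(sigma2=0.0, gamma2=1.0))
        assert rep.total == pytest.approx(2.0)  # D^2 = 2

    def test_group_form_agrees_with_split_form(self, rng):
        """The group-vs-group and subset-vs-full risk expressions agree
        (splitting identity)."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.uniform(-2, 2, size=(r.integers(6, 20), 2))
            t = cre_assign(X.shape[0], n1=int(r.integers(1, X.shape[0])),
                           seed=seed)
            params = RiskParams(sigma2=1.0, gamma2=2.0)
            a = max_risk(t, X, params)
            b = max_risk_split_form(t, X, params)
            assert a.bias_component == pytest.approx(b.bias_component, rel=1e-8)
            assert a.total == pytest.approx(b.total, rel=1e-8)

    def test_report_components_nonnegative_and_additive(self, rng):
        X = rng.normal(size=(12, 2))
        rep = max_risk(cre_assign(12, seed=1), X, RiskParams(1.0, 1.0))
        assert rep.variance_component >= 0 and rep.bias_component >= 0
        assert rep.total == rep.variance_component + rep.bias_component


class TestRandomizationVariance:
    def test_hand_computed_ev(self):
        model = _table_model([1, 2, 3, 4], [0, 0, 0, 0])
        ev, ve = randomization_variance(_index_X(4), model, n1=2)
        assert ev == pytest.approx(5 / 12)
        assert ve == 0.0

    def test_hand_computed_ve(self):
        model = _constant_model(s1=1.0, s0=1.0)
        _, ve = randomization_variance(_index_X(4), model, n1=2)
        assert ve == pytest.approx(1.0)  # 4/8 + 4/8

    def test_constant_means_have_zero_ev(self):
        ev, _ = randomization_variance(_index_X(6), _constant_model(c1=2, c0=1),
                                       n1=3)
        assert ev == pytest.approx(0.0)


class TestEnumerationOracle:
    def test_hand_example_mean_and_variance(self):
        model = _table_model([1, 2, 3, 4], [0, 0, 0, 0])
        mean, var = enumerate_assignment_moments(_index_X(4), model, n1=2)
        assert mean == pytest.approx(2.5)        # unbiasedness: equals tau
        assert var == pytest.approx(5 / 12)      # = 2.5 / 6

    def test_constant_outcomes_have_zero_variance(self):
        _, var = enumerate_assignment_moments(_index_X(6),
                                              _constant_model(c1=1, c0=0), n1=3)
        assert var == pytest.approx(0.0)

    def test_matches_analytic_formula_on_random_instances(self):
        """With no noise, enumeration over all assignments reproduces the
        analytic EV exactly, and the enumerated mean equals the ATE."""
        for seed in range(12):
            r = np.random.default_rng(seed)
            n = int(r.integers(4, 11))
            n1 = int(r.integers(1, n))
            f1 = r.normal(size=n)
            f0 = r.normal(size=n)
            model = _table_model(f1, f0)
            X = _index_X(n)
            mean, var = enumerate_assignment_moments(X, model, n1)
            ev, ve = randomization_variance(X, model, n1)
            assert ve == 0.0
            assert var == pytest.approx(ev, abs=1e-10)
            assert mean == pytest.approx(true_ate(X, model), abs=1e-10)

    def test_noise_adds_analytic_ve(self):
        model = _table_model([1, 2, 3, 4], [0, 0, 0, 0], s1=1.0, s0=1.0)
        _, var = enumerate_assignment_moments(_index_X(4), model, n1=2)
        assert var == pytest.approx(5 / 12 + 1.0)

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="n <= 14"):
            enumerate_assignment_moments(_index_X(16), _constant_model(), 8)


class TestPercentReduction:
    def test_limits(self):
        assert percent_reduction(1.0, 0.0) == 100.0
        assert percent_reduction(2.0, 2.0) == 0.0
        assert percent_reduction(1.0, 2.0) == -100.0

    def test_published_inputs_round_to_94(self):
        # empirical MSEs 129e-4 (randomized) and 8e-4 (optimized)
        assert round(percent_reduction(129e-4, 8e-4)) == 94

    def test_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 0.0)


class TestVaFactor:
    def test_strictly_below_one_and_increasing(self):
        vals = [va_factor(2, a) for a in (0.1, 0.44629, 2.0, 10.0)]
        assert all(v < 1 for v in vals)
        assert vals == sorted(vals)
        # both CDFs saturate for large thresholds, so the ratio tends to 1
        assert va_factor(2, 100.0) == pytest.approx(1.0, abs=1e-12)

    def test_matches_chi_square_cdf_ratio(self):
        a = float(chi2.ppf(0.2, 2))
        assert va_factor(2, a) == pytest.approx(
            chi2.cdf(a, 4) / chi2.cdf(a, 2), rel=1e-12)
        a5 = float(chi2.ppf(0.2, 5))
        assert va_factor(5, a5) == pytest.approx(
            chi2.cdf(a5, 7) / chi2.cdf(a5, 5), rel=1e-12)

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            va_factor(3, 0.0)


def test_percent_reduction_lower_bound_under_noise():
    """With outcome noise, the simulated percent reduction of the optimized
    design stays above EV/(EV+VE) up to Monte Carlo error: the optimized
    design removes (almost) all of the fixed-potential-outcome variance EV
    but none of the noise variance VE."""
    from modesign import SimulationConfig, gen_covariates, run_study
    from modesign.simulate import outcome_model

    n, p, reps = 1000, 5, 150
    res = run_study(SimulationConfig(n=n, p=p, model="C2",
                                     designs=["cre", "mode"],
                                     replications=reps, seed=55))
    model = outcome_model("C2")
    ev, ve = 0.0, 0.0
    for r in range(50):
        e, v = randomization_variance(gen_covariates(n, p, seed=900 + r),
                                      model, n // 2)
        ev += e / 50
        ve += v / 50
    bound = 100.0 * ev / (ev + ve)
    # delta-method MC standard error of PR = 100 (1 - mse_mode / mse_cre)
    se_pr = 100.0 * np.hypot(
        res.mse_se("mode") / res.mse("cre"),
        res.mse("mode") * res.mse_se("cre") / res.mse("cre") ** 2,
    )
    assert res.pr("mode") >= bound - 3 * se_pr


def test_optimal_design_risk_scaling():
    """For the optimized balanced design, n * bias component of the maximum
    risk vanishes while n * variance component equals 4 sigma^2 exactly."""
    params = RiskParams(sigma2=1.0, gamma2=1.0)
    scaled_bias = []
    for n in (64, 256, 1024):
        X = np.random.default_rng(n).uniform(0, 1, size=(n, 2))
        rep = max_risk(mode_assign(X, seed=0), X, params)
        assert n * rep.variance_component == pytest.approx(4.0)
        scaled_bias.append(n * rep.bias_component)
    assert scaled_bias[0] > scaled_bias[1] > scaled_bias[2]
    assert scaled_bias[-1] < 0.1
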