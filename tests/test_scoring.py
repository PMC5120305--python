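import numpy as np
import pytest

from bgrmi.design import RegressionDesign, build_design, build_heterodimers
from bgrmi.scoring import (
    SingularModelError,
    fit_ols,
    log_marginal_likelihood,
    log_posterior,
    score_model,
    zellner_g,
)

from conftest import driven_design
from _oracles import mc_log_marginal


def _design(y, self_lag, candidates, ids):
    n = y.shape[0]
    return RegressionDesign(
        "T", y, np.column_stack([np.ones(n), self_lag]), np.asarray(candidates), list(ids)
    )


class TestFitOls:
    def test_noiseless_sse_zero(self):
        rng = np.random.default_rng(1)
        slag, x = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        y = 0.1 + 0.5 * slag + 2.0 * x
        d = _design(y, slag, x[:, None], ["A"])
        beta, sse = fit_ols(d, ("A",))
        assert sse == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(beta, [0.1, 0.5, 2.0], atol=1e-9)

    def test_null_model_fits_base_only(self):
        rng = np.random.default_rng(2)
        slag = rng.uniform(0, 1, 15)
        y = 1.0 + 0.3 * slag + rng.normal(0, 0.1, 15)
        d = _design(y, slag, np.empty((15, 0)), [])
        beta, sse = fit_ols(d, ())
        assert beta.shape == (2,)
        assert sse > 0

    def test_duplicated_column_is_singular(self):
        rng = np.random.default_rng(3)
        slag, x = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        y = rng.uniform(0, 1, 20)
        d = _design(y, slag, np.column_stack([x, x]), ["A", "B"])
        with pytest.raises(SingularModelError):
            fit_ols(d, ("A", "B"))


class TestZellnerG:
    @pytest.mark.parametrize(
        "n,p_total,expected",
        [(100, 5, 100.0), (20, 10, 100.0), (49, 7, 49.0)],
    )
    def test_benchmark_value(self, n, p_total, expected):
        assert zellner_g(n, p_total) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            zellner_g(0, 5)


class TestMarginalLikelihood:
    def test_scale_equivariance(self):
        """Flat intercept + Jeffreys variance make the marginal scale-
        equivariant: log_ml(c*y) - log_ml(y) = -(n-1) log|c|."""
        rng = np.random.default_rng(4)
        n = 30
        slag, x = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        y = 0.2 + 0.4 * slag + 1.0 * x + rng.normal(0, 0.2, n)
        g = zellner_g(n, 1)
        d0 = _design(y, slag, x[:, None], ["A"])
        base = log_marginal_likelihood(d0, ("A",), g)
        for c in (0.1, 3.0, 100.0):
            dc = _design(c * y, slag, x[:, None], ["A"])
            shifted = log_marginal_likelihood(dc, ("A",), g)
            assert shifted - base == pytest.approx(-(n - 1) * np.log(abs(c)), abs=1e-8)

    def test_monte_carlo_oracle(self):
        """Closed form matches brute-force integration of likelihood x
        priors over (alpha, beta, sigma^2) within 5% relative error."""
        rng = np.random.default_rng(7)
        n = 8
        x = rng.uniform(0, 1, n)
        slag = rng.uniform(0, 1, n)
        y = 0.3 + 0.5 * slag + 0.8 * x + rng.normal(0, 0.2, n)
        c = zellner_g(n, 1)
        d = _design(y, slag, x[:, None], ["A"])
        closed = log_marginal_likelihood(d, ("A",), c)
        mc = mc_log_marginal(y, np.column_stack([slag, x]), c, n_samples=10**7, seed=123)
        assert abs(np.exp(mc - closed) - 1.0) < 0.05

    def test_true_driver_beats_decoy(self):
        ds, regs = driven_design(n=50, sigma=0.05, seed=9)
        d = build_design(ds, regs, "T")
        g = zellner_g(d.n, len(d.candidate_ids))
        ml_true = log_marginal_likelihood(d, ("R0",), g)
        ml_decoy = log_marginal_likelihood(d, ("R1",), g)
        assert ml_true > ml_decoy

    def test_perfect_fit_stays_finite(self):
        rng = np.random.default_rng(5)
        slag, x = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        y = 0.1 + 0.5 * slag + 2.0 * x  # exact
        d = _design(y, slag, x[:, None], ["A"])
        assert np.isfinite(log_marginal_likelihood(d, ("A",), 20.0))

    def test_occam_penalty_on_noise_regressor(self):
        """Adding a pure-noise regressor lowers the posterior in most
        replicates (the marginal's dimension penalty)."""
        wins = 0
        reps = 100
        for rep in range(reps):
            ds, regs = driven_design(n=40, sigma=0.1, seed=1000 + rep, n_candidates=3)
            d = build_design(ds, regs, "T")
            g = zellner_g(d.n, len(d.candidate_ids))
            small = log_marginal_likelihood(d, ("R0",), g)
            big = log_marginal_likelihood(d, ("R0", "R1"), g)
            if small > big:
                wins += 1
        assert wins > reps // 2

    def test_log_space_extremes(self):
        """No overflow across twelve orders of magnitude in noise."""
        rng = np.random.default_rng(6)
        n = 200
        slag, x = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        for sd in (1e-6, 1e6):
            y = 0.3 + 0.5 * slag + x + rng.normal(0, sd, n)
            d = _design(y, slag, x[:, None], ["A"])
            val = log_marginal_likelihood(d, ("A",), zellner_g(n, 1))
            assert np.isfinite(val)


class TestLogPosterior:
    def test_additivity_and_shift(self):
        assert log_posterior(-10.0, 0.0) == -10.0
        assert log_posterior(-10.0, np.log(2.0)) - log_posterior(-10.0, 0.0) == pytest.approx(
            np.log(2.0)
        )

    def test_score_model_consistency(self):
        ds, regs = driven_design(n=30, seed=12)
        d = build_design(ds, regs, "T")
        m = score_model(d, ("R0",), zellner_g(d.n, 4), log_prior=-1.5)
        assert m.log_posterior_unnorm == m.log_marginal + m.log_prior
        assert m.p == 2  # self-lag + one regulator
        assert m.beta_hat.shape == (3,)

    def test_singular_subset_scores_minus_inf(self):
        rng = np.random.default_rng(8)
        slag, x = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        d = _design(rng.uniform(0, 1, 20), slag, np.column_stack([x, x]), ["A", "B"])
        m = score_model(d, ("A", "B"), 20.0, 0.0)
        assert m.log_posterior_unnorm == -np.inf
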