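import math

import numpy as np
import pytest

from sentinet.ou import (
    OUSystem,
    SignalMoments,
    StabilityError,
    coefficient_of_variation,
    d_statistic,
    read_covariance_csv,
    signal_moments,
    solve_lyapunov,
    write_covariance_csv,
)

from conftest import random_psd, random_stable_drift


class TestSolveLyapunov:
    def test_scalar_ou_stationary_variance(self):
        """A = a I, B = sigma I gives the textbook variance sigma^2 / (2a)."""
        a, sigma = 1.7, 0.3
        c = solve_lyapunov(OUSystem(a * np.eye(3), sigma * np.eye(3)))
        assert np.allclose(c, sigma**2 / (2 * a) * np.eye(3), atol=1e-14)

    @pytest.mark.parametrize("seed", range(10))
    def test_residual_and_psd_on_random_stable_systems(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        a = random_stable_drift(rng, n)
        b = np.diag(rng.uniform(0.1, 1.0, size=n))
        c = solve_lyapunov(OUSystem(a, b))
        q = b @ b.T
        assert np.abs(a @ c + c @ a.T - q).max() < 1e-10 * np.abs(q).max()
        assert np.array_equal(c, c.T)
        assert np.linalg.eigvalsh(c).min() > -1e-12

    def test_unstable_drift_raises_naming_eigenvalue(self):
        a = np.array([[-1.0, 0.0], [0.0, 2.0]])
        with pytest.raises(StabilityError, match="eigenvalue"):
            solve_lyapunov(OUSystem(a, np.eye(2)))

    def test_matches_ensemble_euler_maruyama_simulation(self):
        """Stationary covariance agrees with an ensemble SDE simulation.

        2000 independent replicas of dz = -A z dt + B dW are integrated well
        past the mixing time; the final-state sample covariance must match
        the Lyapunov solution within 3 Monte-Carlo standard errors.
        """
        rng = np.random.default_rng(99)
        n = 5
        a = random_stable_drift(rng, n)
        b = np.diag(rng.uniform(0.2, 0.8, size=n))
        c_exact = solve_lyapunov(OUSystem(a, b))
        n_rep, dt = 2000, 0.002
        t_end = 8.0 / np.linalg.eigvals(a).real.min()
        z = np.zeros((n_rep, n))
        sqrt_dt = math.sqrt(dt)
        for _ in range(int(t_end / dt)):
            noise = rng.standard_normal((n_rep, n))
            z = z - z @ a.T * dt + noise @ b.T * sqrt_dt
        c_emp = np.cov(z, rowvar=False)
        se = np.sqrt(
            (np.outer(np.diag(c_exact), np.diag(c_exact)) + c_exact**2) / n_rep
        )
        assert np.all(np.abs(c_emp - c_exact) <= 3 * se + 0.02 * np.abs(c_exact))


class TestSignalMoments:
    def test_single_node(self):
        c = np.array([[0.7]])
        m = signal_moments(c, [0], 50)
        assert m.mean == pytest.approx(0.7)
        assert m.variance == pytest.approx(2 * 0.7**2 / 49)

    @pytest.mark.parametrize("seed", range(5))
    def test_trace_form_equals_eigenvalue_form(self, seed):
        """Sum of squared entries of the principal submatrix = sum lambda_i^2."""
        rng = np.random.default_rng(seed)
        c = random_psd(rng, 6)
        members = [0, 2, 5]
        m = signal_moments(c, members, 100)
        lam = np.linalg.eigvalsh(c[np.ix_(members, members)])
        n = len(members)
        assert m.mean == pytest.approx(lam.sum() / n, rel=1e-10)
        assert m.variance == pytest.approx(
            2 / (n**2 * 99) * (lam**2).sum(), rel=1e-10
        )

    def test_uncorrelated_equal_variance_cv(self):
        """CV for n uncorrelated equal-variance nodes is sqrt(2/(L-1))/sqrt(n)."""
        for n, sample_size in [(2, 100), (4, 10), (7, 1000)]:
            c = 0.3 * np.eye(n)
            m = signal_moments(c, range(n), sample_size)
            assert m.cv == pytest.approx(
                math.sqrt(2 / (sample_size - 1)) / math.sqrt(n)
            )

    def test_sample_size_must_be_at_least_two(self):
        with pytest.raises(ValueError, match="sample size"):
            signal_moments(np.eye(2), [0], 1)

    def test_node_set_validation(self):
        with pytest.raises(ValueError, match="out of range"):
            signal_moments(np.eye(2), [0, 2], 10)
        with pytest.raises(ValueError, match="duplicate"):
            signal_moments(np.eye(3), [1, 1], 10)
        with pytest.raises(ValueError, match="at least one"):
            signal_moments(np.eye(3), [], 10)

    def test_monte_carlo_oracle_on_chain_covariance(self, chain_scenarios):
        """Moment formulas match 10^5 empirical draws of the averaged variance.

        Each replicate draws L i.i.d. Gaussian vectors with the chain's
        stationary covariance and computes the node-averaged sample variance;
        the empirical mean and variance of that statistic must agree with the
        formulas within 3 standard errors.
        """
        from sentinet.analytic import chain_covariance

        c = chain_covariance(chain_scenarios[1])
        sample_size, reps = 100, 100_000
        members = [0, 1, 2]
        m = signal_moments(c, members, sample_size)
        rng = np.random.default_rng(7)
        chol = np.linalg.cholesky(c)
        v_hat = np.empty(reps)
        for start in range(0, reps, 10_000):  # chunked to bound memory
            block = slice(start, start + 10_000)
            z = rng.standard_normal((10_000, sample_size, 3)) @ chol.T
            v_hat[block] = z.var(axis=1, ddof=1).mean(axis=1)
        se_mean = v_hat.std(ddof=1) / math.sqrt(reps)
        assert abs(v_hat.mean() - m.mean) <= 3 * se_mean
        sq_dev = (v_hat - v_hat.mean()) ** 2
        se_var = sq_dev.std(ddof=1) / math.sqrt(reps)
        assert abs(v_hat.var(ddof=1) - m.variance) <= 3 * se_var


class TestCoefficientOfVariation:
    def test_single_node_value_is_universal(self):
        """Any single node has CV = sqrt(2/(L-1)), here 0.1421 for L=100."""
        m = signal_moments(np.array([[123.4]]), [0], 100)
        assert coefficient_of_variation(m) == pytest.approx(
            math.sqrt(2 / 99), abs=1e-12
        )
        assert round(m.cv, 4) == 0.1421

    def test_two_equal_eigenvalues_shrink_cv_by_sqrt2(self):
        m1 = signal_moments(np.eye(1), [0], 100)
        m2 = signal_moments(np.eye(2), [0, 1], 100)
        assert m2.cv == pytest.approx(m1.cv / math.sqrt(2))

    def test_degenerate_rank_one_matches_single_node(self):
        c = np.array([[1.0, 1.0], [1.0, 1.0]])  # eigenvalues (2, 0)
        m = signal_moments(c, [0, 1], 100)
        assert m.cv == pytest.approx(math.sqrt(2 / 99))

    @pytest.mark.parametrize("seed", range(5))
    def test_adding_an_imperfectly_correlated_node_reduces_cv(self, seed):
        rng = np.random.default_rng(seed)
        c = random_psd(rng, 4) + 0.1 * np.eye(4)  # full rank => not degenerate
        single = signal_moments(c, [0], 100).cv
        for extra in (1, 2, 3):
            assert signal_moments(c, [0, extra], 100).cv < single

    @pytest.mark.parametrize("sample_size", [3, 10, 100, 1000])
    def test_cv_scales_as_inverse_sqrt_sample_size(self, sample_size, rng):
        c = random_psd(rng, 3)
        m = signal_moments(c, [0, 1, 2], sample_size)
        invariant = m.cv * math.sqrt(sample_size - 1)
        c_ref = signal_moments(c, [0, 1, 2], 100)
        assert invariant == pytest.approx(c_ref.cv * math.sqrt(99), rel=1e-10)

    def test_nonpositive_mean_raises(self):
        with pytest.raises(ValueError, match="mean"):
            coefficient_of_variation(SignalMoments(0.0, 1.0, 100))


class TestDStatistic:
    def test_identical_distributions_give_zero(self):
        m = SignalMoments(1.0, 0.5, 100)
        assert d_statistic(m, m) == 0.0

    def test_hand_computed_value(self):
        assert d_statistic(
            SignalMoments(0.0, 1.0, 10), SignalMoments(2.0, 3.0, 10)
        ) == pytest.approx(1.0)

    def test_symmetric_under_swap(self):
        m1, m2 = SignalMoments(0.3, 0.2, 10), SignalMoments(1.1, 0.7, 10)
        assert d_statistic(m1, m2) == d_statistic(m2, m1)

    @pytest.mark.parametrize("scale", [0.1, 2.0, 1e6])
    def test_invariant_under_common_rescaling(self, scale):
        m1, m2 = SignalMoments(0.3, 0.2, 10), SignalMoments(1.1, 0.7, 10)
        s1 = SignalMoments(scale * m1.mean, scale**2 * m1.variance, 10)
        s2 = SignalMoments(scale * m2.mean, scale**2 * m2.variance, 10)
        assert d_statistic(s1, s2) == pytest.approx(d_statistic(m1, m2))

    def test_zero_variances_raise(self):
        with pytest.raises(ValueError, match="variances"):
            d_statistic(SignalMoments(1.0, 0.0, 10), SignalMoments(2.0, 0.0, 10))


def test_covariance_csv_round_trip(tmp_path, rng):
    c = random_psd(rng, 4)
    path = tmp_path / "cov.csv"
    write_covariance_csv(c, path, labels=list("abcd"))
    back, labels = read_covariance_csv(path)
    assert labels == ("a", "b", "c", "d")
    assert np.allclose(back, c)
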