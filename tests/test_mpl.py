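"""Closed-form estimator, path likelihood, and confidence-interval checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from mplselect import (
    EvolutionParams,
    MonomorphicTrajectoryError,
    ObservedTrajectory,
    integrated_variance,
    likelihood_ratio_ci,
    log_likelihood,
    s_hat,
    s_mpl,
    simulate,
)
from mplselect.mpl import s_hat_batch, s_mpl_batch


def random_polymorphic_trajectory(rng, K=8):
    """Short random trajectory bounded away from 0/1 (for likelihood oracles)."""
    freqs = rng.uniform(0.1, 0.9, size=K + 1)
    dts = rng.integers(1, 15, size=K).astype(float)
    return freqs, dts


class TestIntegratedVariance:
    def test_lost_trajectory_is_zero(self):
        assert integrated_variance(np.zeros(5), np.ones(4)) == 0.0

    def test_constant_half_closed_form(self):
        # v = 0.25 at each of K=3 retained points, dt = 10 -> 7.5
        assert integrated_variance(np.full(4, 0.5), np.full(3, 10.0)) == 7.5

    def test_monotone_under_extension(self, det_sampled):
        x, dts = det_sampled
        partial = [integrated_variance(x[: k + 1], dts[:k]) for k in range(1, len(x))]
        assert np.all(np.diff(partial) >= 0)

    def test_matches_high_precision_summation(self, det_sampled):
        from fractions import Fraction

        x, dts = det_sampled
        exact = sum(
            Fraction(t) * Fraction(xi) * (1 - Fraction(xi))
            for t, xi in zip(dts, x[:-1])
        )
        assert integrated_variance(x, dts) == pytest.approx(float(exact), rel=1e-12)


class TestSMPL:
    def test_exact_recovery_on_linearized_trajectory(self):
        # the estimator inverts the linearized recursion exactly when every
        # generation is retained
        params = EvolutionParams(N=1000, s=0.02, mu=1e-3, x0=0.1)
        traj = simulate(params, 450, model="det_linear")
        est = s_mpl(traj.freqs, np.diff(traj.times).astype(float), 1e-3)
        assert est == pytest.approx(0.02, abs=1e-12)

    @given(
        s=st.floats(-0.05, 0.05),
        mu=st.floats(0, 5e-3),
        x0=st.floats(0.05, 0.95),
    )
    @settings(deadline=None, max_examples=50)
    def test_exact_recovery_property(self, s, mu, x0):
        params = EvolutionParams(N=1000, s=s, mu=mu, x0=x0)
        traj = simulate(params, 100, model="det_linear")
        if (traj.freqs[:-1] * (1 - traj.freqs[:-1])).sum() == 0:
            return  # absorbed immediately; estimator undefined by design
        est = s_mpl(traj.freqs, np.ones(100), mu)
        assert est == pytest.approx(s, abs=1e-10)

    def test_neutral_constant_trajectory_gives_zero(self):
        assert s_mpl(np.full(5, 0.5), np.ones(4), 0.0) == 0.0

    def test_grid_argmax_oracle(self, rng):
        # independent oracle: dense grid search of the path log-likelihood
        for _ in range(5):
            freqs, dts = random_polymorphic_trajectory(rng)
            est = s_mpl(freqs, dts, 1e-3)
            grid = np.linspace(est - 0.3, est + 0.3, 20_001)
            lls = [log_likelihood(s, freqs, dts, 500, 1e-3) for s in grid]
            assert abs(grid[np.argmax(lls)] - est) <= (grid[1] - grid[0])

    @given(
        s=st.floats(-0.04, 0.04),
        x0=st.floats(0.1, 0.9),
    )
    @settings(deadline=None, max_examples=50)
    def test_relabeling_antisymmetry(self, s, x0):
        # swapping allele labels (x -> 1-x) negates the estimate
        params = EvolutionParams(N=1000, s=s, mu=1e-3, x0=x0)
        traj = simulate(params, 60, model="det_exact")
        dts = np.ones(60)
        a = s_mpl(traj.freqs, dts, 1e-3)
        b = s_mpl(1 - traj.freqs, dts, 1e-3)
        assert a == pytest.approx(-b, abs=1e-10)

    def test_monomorphic_trajectory_raises(self):
        with pytest.raises(MonomorphicTrajectoryError):
            s_mpl(np.ones(5), np.ones(4), 0.0)

    def test_batch_matches_scalar(self, rng):
        freqs = rng.uniform(0.05, 0.95, size=(20, 6))
        dts = np.full(5, 10.0)
        batch = s_mpl_batch(freqs, dts, 1e-3)
        for row, est in zip(freqs, batch):
            assert est == pytest.approx(s_mpl(row, dts, 1e-3), rel=1e-13)


class TestSHat:
    def test_reduces_to_s_mpl_without_noise_or_correction(self, det_sampled):
        x, dts = det_sampled
        ns = 1000
        counts = np.round(x * ns).astype(int)
        obs = ObservedTrajectory(
            times=np.arange(0, 451, 10), sizes=np.full(len(x), ns), counts=counts
        )
        est = s_hat(obs, 1e-3, bias_correction=False)
        assert est.s_hat == pytest.approx(s_mpl(obs.freqs, dts, 1e-3), rel=1e-12)

    @pytest.mark.parametrize("ns", [2, 3, 5, 8])
    def test_bias_correction_is_exactly_unbiased(self, ns):
        # E[ns/(ns-1) * vhat] enumerated over all binomial outcomes equals v
        for x in [0.1, 0.3, 0.5, 0.77]:
            c = np.arange(ns + 1)
            pmf = binom.pmf(c, ns, x)
            corrected = (ns / (ns - 1)) * (c / ns) * (1 - c / ns)
            assert np.dot(pmf, corrected) == pytest.approx(x * (1 - x), abs=1e-12)

    def test_mean_matches_first_order_theory(self, study_params, study_design, det_trajectory):
        # E[s^] equals the perfect-sampling estimate to first order; the
        # allowance covers the second-order ratio bias (~0.4% relative here)
        from mplselect.evolve import observe_counts

        x = det_trajectory.at(study_design.times)
        dts = study_design.dts.astype(float)
        rng = np.random.default_rng(5)
        sizes = np.asarray(study_design.ns)
        counts = observe_counts(x, sizes, 10_000, rng)
        est = s_hat_batch(counts, sizes, dts, study_params.mu)
        se = est.std(ddof=1) / np.sqrt(len(est))
        target = s_mpl(x, dts, study_params.mu)
        assert abs(est.mean() - target) < 3 * se + 1.5e-4

    def test_uninformative_observation_raises(self):
        obs = ObservedTrajectory(
            times=np.array([0, 10, 20]),
            sizes=np.array([5, 5, 5]),
            counts=np.array([0, 0, 5]),
        )
        with pytest.raises(MonomorphicTrajectoryError, match="uninformative"):
            s_hat(obs, 0.0)

    def test_batch_matches_scalar(self, rng):
        sizes = np.array([12, 20, 8, 15])
        counts = rng.binomial(sizes, 0.4, size=(15, 4))
        dts = np.array([10.0, 10.0, 10.0])
        batch = s_hat_batch(counts, sizes, dts, 1e-3)
        for row, est in zip(counts, batch):
            obs = ObservedTrajectory(times=np.arange(0, 40, 10), sizes=sizes, counts=row)
            if np.isnan(est):
                with pytest.raises(MonomorphicTrajectoryError):
                    s_hat(obs, 1e-3)
            else:
                assert est == pytest.approx(s_hat(obs, 1e-3).s_hat, rel=1e-13)


class TestLogLikelihood:
    def test_curvature_is_minus_N_times_V(self, rng):
        freqs, dts = random_polymorphic_trajectory(rng)
        N = 800
        h = 1e-4
        second = (
            log_likelihood(0.02 + h, freqs, dts, N, 1e-3)
            - 2 * log_likelihood(0.02, freqs, dts, N, 1e-3)
            + log_likelihood(0.02 - h, freqs, dts, N, 1e-3)
        ) / h**2
        assert second == pytest.approx(-N * integrated_variance(freqs, dts), rel=1e-4)

    def test_exactly_quadratic_about_maximum(self, rng):
        freqs, dts = random_polymorphic_trajectory(rng)
        N, mu = 1200, 1e-3
        s_max = s_mpl(freqs, dts, mu)
        ll_max = log_likelihood(s_max, freqs, dts, N, mu)
        v_raw = integrated_variance(freqs, dts)
        for s in np.linspace(s_max - 0.2, s_max + 0.2, 9):
            expected = ll_max - 0.5 * N * v_raw * (s - s_max) ** 2
            assert log_likelihood(s, freqs, dts, N, mu) == pytest.approx(expected, abs=1e-8)

    def test_likelihood_ratio_vanishes_at_maximum(self, rng):
        freqs, dts = random_polymorphic_trajectory(rng)
        s_max = s_mpl(freqs, dts, 1e-3)
        lr = -2 * (
            log_likelihood(s_max, freqs, dts, 500, 1e-3)
            - log_likelihood(s_max, freqs, dts, 500, 1e-3)
        )
        assert lr == 0.0

    def test_degenerate_transitions_dropped_with_warning(self):
        freqs = np.array([0.0, 0.2, 0.5])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            ll = log_likelihood(0.01, freqs, np.ones(2), 100, 1e-3)
        assert np.isfinite(ll)


class TestConfidenceInterval:
    def test_contains_and_symmetric_about_argmax(self, rng):
        freqs, dts = random_polymorphic_trajectory(rng)
        lo, hi = likelihood_ratio_ci(freqs, dts, 1000, 1e-3)
        center = s_mpl(freqs, dts, 1e-3)
        assert lo < center < hi
        assert (center - lo) == pytest.approx(hi - center, rel=1e-10)

    def test_matches_bisection_on_likelihood_ratio(self, rng):
        # independent oracle: bisect -2[l(s0) - l(s^)] = chi2 threshold
        from scipy.optimize import brentq
        from scipy.stats import chi2

        freqs, dts = random_polymorphic_trajectory(rng)
        N, mu = 700, 1e-3
        lo, hi = likelihood_ratio_ci(freqs, dts, N, mu)
        s_max = s_mpl(freqs, dts, mu)
        ll_max = log_likelihood(s_max, freqs, dts, N, mu)
        thresh = chi2.ppf(0.95, df=1)

        def lr(s0):
            return -2 * (log_likelihood(s0, freqs, dts, N, mu) - ll_max) - thresh

        assert brentq(lr, s_max, s_max + 10) == pytest.approx(hi, abs=1e-8)
        assert brentq(lr, s_max - 10, s_max) == pytest.approx(lo, abs=1e-8)

    def test_halfwidth_scales_inverse_sqrt_N(self, rng):
        freqs, dts = random_polymorphic_trajectory(rng)
        lo1, hi1 = likelihood_ratio_ci(freqs, dts, 1000, 1e-3)
        lo2, hi2 = likelihood_ratio_ci(freqs, dts, 2000, 1e-3)
        assert (hi2 - lo2) == pytest.approx((hi1 - lo1) / np.sqrt(2), rel=1e-10)
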