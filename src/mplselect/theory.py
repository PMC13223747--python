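"""Analytical performance theory of the MPL estimator, with Monte-Carlo audits.

The estimator ``s^ = D^ / V^`` is a ratio of correlated random variables.  A
first-order multivariate Taylor expansion about the means gives its moments
under binomial sampling of a fixed (deterministic) trajectory:

* mean: ``E[s^] = E[D^]/E[V^]`` = the perfect-sampling estimate, hence the
  true ``s`` on a deterministic trajectory;
* variance: ``Var[s^] = Var[D^]/V^2 - 2 s Cov[D^,V^]/V^2 + s^2 Var[V^]/V^2``
  with closed forms for the three components (exact under binomial sampling
  with constant sample size and sampling step);
* order: ``Var[s^] = O(ns^-1 V^-2)`` in the sample size and integrated
  variance.

Under genetic drift the variance decomposes empirically into a sampling-only
and a drift-only term, ``Var[s^] ~ sigma_s^2 + sigma_d^2``; the drift term is
bounded below by the Cramer-Rao limit ``1/(N V)`` (the Fisher information of
the Gaussian path likelihood is ``N V``), and the bound is tight for
moderate-to-large N.  The total variance feeds a detection-power analysis:
the smallest selection coefficient detectable at the 5% level solves
``Var[s^](s) = (s/2)^2``.

Monte-Carlo helpers here are vectorized across replicates (time-major draws)
and report standard errors so "agrees within k SE" statements are
well-defined.  Replicates where the estimator is undefined (all retained
samples monomorphic) are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .evolve import EvolutionParams, SamplingDesign, observe_counts, simulate, wf_ensemble
from .mpl import s_hat_batch, s_mpl, s_mpl_batch

__all__ = [
    "VarianceReport",
    "MonteCarloSummary",
    "analytic_mean",
    "var_D",
    "cov_DV",
    "var_V",
    "var_s_sampling",
    "crlb_drift",
    "var_total",
    "variance_report",
    "summarize_estimates",
    "sampling_only_variance_empirical",
    "drift_only_variance_empirical",
    "joint_variance_empirical",
    "gaussian_approx",
    "kl_to_standard_normal",
    "min_detectable_s",
]


@dataclass(frozen=True)
class VarianceReport:
    """Analytic moment components for a given trajectory/design."""

    mean_s: float
    var_D: float
    cov_DV: float
    var_V: float
    var_s_sampling: float
    crlb_drift: float
    var_total: float
    V: float


@dataclass(frozen=True)
class MonteCarloSummary:
    """Empirical moments of an estimator over seeded replicates.

    ``se_var`` uses the fourth-central-moment formula
    ``Var(s^2) = (m4 - sigma^4 (n-3)/(n-1)) / n``.
    """

    n_reps: int
    n_failed: int
    mean: float
    variance: float
    se_mean: float
    se_var: float


def _require_constant(arr, name: str) -> float:
    arr = np.asarray(arr, dtype=np.float64)
    if not np.all(arr == arr.flat[0]):
        raise ValueError(f"the closed-form moment formulas assume a constant {name}")
    return float(arr.flat[0])


def _traj_pieces(freqs, dts):
    freqs = np.asarray(freqs, dtype=np.float64)
    dts = np.asarray(dts, dtype=np.float64)
    if len(dts) != len(freqs) - 1:
        raise ValueError("need K+1 frequencies and K time steps")
    dt = _require_constant(dts, "time sampling step")
    v = freqs * (1 - freqs)
    V = dt * v[:-1].sum()
    return freqs, v, dt, V


def analytic_mean(freqs, dts, mu: float) -> float:
    """First-order Taylor mean of s^: the perfect-sampling estimate itself."""
    return s_mpl(freqs, dts, mu)


def var_D(freqs, dts, ns: int, mu: float) -> float:
    """Variance of the numerator D^ under binomial sampling (exact).

    ``Var[D^] = [v(t_K) + v(t_0) - 4 mu dt v(t_0) + 4 mu^2 dt V] / ns``.
    """
    x, v, dt, V = _traj_pieces(freqs, dts)
    return (v[-1] + v[0] - 4 * mu * dt * v[0] + 4 * mu**2 * dt * V) / ns


def cov_DV(freqs, dts, ns: int, mu: float) -> float:
    """Covariance of D^ with the bias-corrected denominator V^ (exact).

    ``Cov[D^,V^] = -(dt/ns) [v(t_0)(1-2x(t_0))
                             - 2 mu dt sum_k v(t_k)(1-2x(t_k))]``.
    """
    x, v, dt, V = _traj_pieces(freqs, dts)
    tail = np.dot(v[:-1], 1 - 2 * x[:-1])
    return -(dt / ns) * (v[0] * (1 - 2 * x[0]) - 2 * mu * dt * tail)


def var_V(freqs, dts, ns: int) -> float:
    """Variance of the bias-corrected denominator V^ (exact).

    ``Var[V^] = (dt/ns) [V - (4 - 2/(ns-1)) dt sum_k v(t_k)^2]``.
    """
    x, v, dt, V = _traj_pieces(freqs, dts)
    return (dt / ns) * (V - (4 - 2 / (ns - 1)) * dt * np.sum(v[:-1] ** 2))


def var_s_sampling(freqs, dts, ns: int, mu: float) -> float:
    """Taylor-series sampling variance of s^ on a fixed trajectory.

    Combines the three moment components with the perfect-sampling estimate;
    scales as ``O(ns^-1 V^-2)``.
    """
    x, v, dt, V = _traj_pieces(freqs, dts)
    m = analytic_mean(freqs, dts, mu)
    return (
        var_D(freqs, dts, ns, mu)
        - 2 * m * cov_DV(freqs, dts, ns, mu)
        + m**2 * var_V(freqs, dts, ns)
    ) / V**2


def crlb_drift(N: int, V: float) -> float:
    """Cramer-Rao lower bound on the drift-only variance: 1 / (N V)."""
    if N <= 0 or V <= 0:
        raise ValueError("N and V must be positive")
    return 1.0 / (N * V)


def var_total(freqs, dts, ns: int, N: int, mu: float) -> float:
    """Total estimator variance: sampling-only term + CRLB drift plug-in.

    ``freqs`` should be the mean (deterministic) population trajectory; the
    CRLB is used for the drift component since the bound is tight when N is
    not small.
    """
    x, v, dt, V = _traj_pieces(freqs, dts)
    return var_s_sampling(freqs, dts, ns, mu) + crlb_drift(N, V)


def variance_report(freqs, dts, ns: int, N: int, mu: float) -> VarianceReport:
    """All analytic moment quantities for one trajectory/design in one object."""
    x, v, dt, V = _traj_pieces(freqs, dts)
    return VarianceReport(
        mean_s=analytic_mean(freqs, dts, mu),
        var_D=var_D(freqs, dts, ns, mu),
        cov_DV=cov_DV(freqs, dts, ns, mu),
        var_V=var_V(freqs, dts, ns),
        var_s_sampling=var_s_sampling(freqs, dts, ns, mu),
        crlb_drift=crlb_drift(N, V),
        var_total=var_total(freqs, dts, ns, N, mu),
        V=V,
    )


def summarize_estimates(estimates: np.ndarray) -> MonteCarloSummary:
    """Empirical mean/variance of estimates, excluding NaNs (failed replicates)."""
    estimates = np.asarray(estimates, dtype=np.float64)
    n_reps = len(estimates)
    ok = estimates[np.isfinite(estimates)]
    n = len(ok)
    if n < 2:
        raise ValueError("fewer than two defined replicates; cannot summarize")
    mean = ok.mean()
    var = ok.var(ddof=1)
    m4 = np.mean((ok - mean) ** 4)
    se_var = np.sqrt(max(m4 - var**2 * (n - 3) / (n - 1), 0.0) / n)
    return MonteCarloSummary(
        n_reps=n_reps,
        n_failed=n_reps - n,
        mean=float(mean),
        variance=float(var),
        se_mean=float(np.sqrt(var / n)),
        se_var=float(se_var),
    )


def _mean_trajectory(
    params: EvolutionParams,
    design: SamplingDesign,
    mean_model: str,
    n_wf_mean: int,
    rng: np.random.Generator,
) -> np.ndarray:
    T = max(design.times)
    if mean_model == "det_exact":
        return simulate(params, T, model="det_exact").at(design.times)
    if mean_model == "wf_mean":
        ens = wf_ensemble(params, T, n_wf_mean, rng, record_times=design.times)
        return ens.mean(axis=0)
    raise ValueError(f"unknown mean_model {mean_model!r}")


def sampling_only_variance_empirical(
    params: EvolutionParams,
    design: SamplingDesign,
    n_reps: int,
    seed: int | None = None,
    mean_model: str = "det_exact",
    n_wf_mean: int = 1000,
) -> MonteCarloSummary:
    """Variance of s^ over repeated observations of one fixed mean trajectory.

    The mean population trajectory is the exact deterministic one by default
    (it closely tracks the WF ensemble mean); pass ``mean_model='wf_mean'``
    to average ``n_wf_mean`` WF replicates instead.
    """
    rng = np.random.default_rng(seed)
    x = _mean_trajectory(params, design, mean_model, n_wf_mean, rng)
    sizes = design.realize_sizes(rng)
    counts = observe_counts(x, sizes, n_reps, rng)
    est = s_hat_batch(counts, sizes, design.dts, params.mu)
    return summarize_estimates(est)


def drift_only_variance_empirical(
    params: EvolutionParams,
    times,
    n_reps: int,
    seed: int | None = None,
) -> MonteCarloSummary:
    """Variance of the perfect-sampling estimate over WF trajectory replicates."""
    times = np.asarray(times, dtype=np.int64)
    rng = np.random.default_rng(seed)
    freqs = wf_ensemble(params, int(times.max()), n_reps, rng, record_times=times)
    est = s_mpl_batch(freqs, np.diff(times), params.mu)
    return summarize_estimates(est)


def joint_variance_empirical(
    params: EvolutionParams,
    design: SamplingDesign,
    n_reps: int,
    seed: int | None = None,
) -> MonteCarloSummary:
    """Moments of s^ under joint drift + limited-sampling noise (WF ensemble)."""
    rng = np.random.default_rng(seed)
    T = max(design.times)
    freqs = wf_ensemble(params, T, n_reps, rng, record_times=design.times)
    sizes = design.realize_sizes(rng)
    counts = observe_counts(freqs, sizes, n_reps, rng)
    est = s_hat_batch(counts, sizes, design.dts, params.mu)
    return summarize_estimates(est)


def gaussian_approx(freqs, dts, ns: int, mu: float) -> tuple[float, float]:
    """Parameters (mean, variance) of the asymptotic normal approximation of s^.

    Valid as the integrated variance grows (long polymorphic trajectories):
    the mean is the perfect-sampling estimate and the variance the
    Taylor-series sampling variance.
    """
    return analytic_mean(freqs, dts, mu), var_s_sampling(freqs, dts, ns, mu)


def kl_to_standard_normal(samples, bins: str | int = "scott") -> float:
    """KL divergence (nats) of a standardized sample from N(0, 1).

    Standardizes to zero mean / unit variance, histograms (Scott-rule bins by
    default), and sums ``p log(p/q)`` with ``q`` the normal mass per bin.
    Empty bins contribute zero.
    """
    z = np.asarray(samples, dtype=np.float64)
    if len(z) < 10:
        raise ValueError("too few samples for a histogram KL estimate")
    z = (z - z.mean()) / z.std(ddof=0)
    hist, edges = np.histogram(z, bins=bins)
    p = hist / hist.sum()
    q = np.diff(norm.cdf(edges))
    mask = (p > 0) & (q > 0)
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def min_detectable_s(
    N: int,
    ns: int = 20,
    dt: int = 10,
    T: int = 150,
    x0: float = 0.1,
    mu: float = 1e-3,
    bracket: tuple[float, float] = (1e-4, 1.0),
    tol: float = 1e-5,
    n_scan: int = 200,
) -> float:
    """Smallest selection coefficient detectable at the 5% significance level.

    Solves the fixed point ``var_total(s) = (s/2)^2``, where the trajectory
    (hence the integrated variance) is rebuilt per candidate ``s`` from the
    exact deterministic model.  The objective can cross zero twice on the
    bracket (the variance grows superquadratically at very strong selection),
    so the bracket is scanned geometrically for the first sign change and the
    root is then bisected within it.
    """
    if T % dt != 0:
        raise ValueError(f"T={T} must be a multiple of dt={dt}")
    times = np.arange(0, T + 1, dt)
    dts = np.diff(times)

    def objective(s: float) -> float:
        params = EvolutionParams(N=N, s=s, mu=mu, x0=x0)
        x = simulate(params, T, model="det_exact").at(times)
        return var_total(x, dts, ns, N, mu) - (s / 2) ** 2

    grid = np.geomspace(bracket[0], bracket[1], n_scan)
    vals = np.array([objective(s) for s in grid])
    signs = np.sign(vals)
    crossings = np.flatnonzero(signs[:-1] * signs[1:] < 0)
    if len(crossings) == 0:
        raise ValueError(
            "no sign change of var_total(s) - (s/2)^2 in the bracket "
            f"{bracket}: endpoint values {vals[0]:.3g}, {vals[-1]:.3g}"
        )
    i = crossings[0]
    return float(brentq(objective, grid[i], grid[i + 1], xtol=tol))
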