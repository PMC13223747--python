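"""Closed-form MPL selection-coefficient estimators and likelihood machinery.

The marginal path likelihood (MPL) approximates the Wright-Fisher transition
probability by a Gaussian in the frequency increment, with drift
``dt (s v + mu (1 - 2x))`` and variance ``dt v / N`` where ``v = x (1 - x)``.
Maximizing the resulting path likelihood in ``s`` is a quadratic problem with
the closed-form solution

    s_MPL = [x(t_K) - x(t_0) - mu * sum_k dt_k (1 - 2 x(t_k))]
            / sum_k dt_k v(t_k),

the sums running over k = 0..K-1.  When only sampled frequencies are
available, plugging them in biases the denominator because the sample
variance ``x^ (1 - x^)`` underestimates the population variance; the
per-time factor ``ns / (ns - 1)`` corrects this exactly under binomial
sampling, giving the practical estimator ``s^ = D^ / V^``.

Zero-variance time points (frequency fixed or lost at a retained time)
contribute nothing to the denominator but keep their mutation-flux term, as
the formula is written; the estimator errors only when the denominator
vanishes entirely (fully monomorphic data).  The path likelihood, whose
transition density is degenerate at zero variance, drops such transitions
with a warning instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .evolve import ObservedTrajectory

__all__ = [
    "MonomorphicTrajectoryError",
    "MPLEstimate",
    "integrated_variance",
    "s_mpl",
    "s_mpl_batch",
    "s_hat",
    "s_hat_batch",
    "log_likelihood",
    "likelihood_ratio_ci",
]


class MonomorphicTrajectoryError(ValueError):
    """All retained time points carry zero allele variance: s is unidentifiable."""


@dataclass(frozen=True)
class MPLEstimate:
    """Result of the closed-form estimator s^ = D^ / V^.

    ``numerator`` is the net frequency change minus the mutation flux;
    ``denominator`` the (optionally bias-corrected) integrated sample
    variance.  ``ci_low``/``ci_high`` hold the likelihood-ratio confidence
    interval when requested (centered on the likelihood argmax, which is the
    uncorrected estimate).
    """

    s_hat: float
    numerator: float
    denominator: float
    bias_corrected: bool = True
    ci_low: float | None = None
    ci_high: float | None = None


def _check_lengths(freqs: np.ndarray, dts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.asarray(freqs, dtype=np.float64)
    dts = np.asarray(dts, dtype=np.float64)
    if freqs.ndim != 1 or dts.ndim != 1 or len(dts) != len(freqs) - 1:
        raise ValueError("need K+1 frequencies and K time steps")
    if (dts < 1).any():
        raise ValueError("time steps must be >= 1 generation")
    return freqs, dts


def integrated_variance(freqs, dts) -> float:
    """Integrated allele variance V = sum_k dt_k x(t_k)(1 - x(t_k)), k = 0..K-1.

    The final time point is excluded, matching the transition sums of the
    path likelihood.  V is the precision-determining quantity of MPL-based
    estimation: both noise components shrink as it grows.
    """
    freqs, dts = _check_lengths(freqs, dts)
    v = freqs[:-1] * (1 - freqs[:-1])
    return float(np.dot(dts, v))


def _numerator_denominator(freqs: np.ndarray, dts: np.ndarray, mu: float,
                           correction: np.ndarray | None = None) -> tuple[float, float]:
    """Shared D/V computation.

    All terms enter the sums as written: time points with zero allele
    variance contribute nothing to the denominator but their mutation-flux
    term is kept (dropping it measurably biases the estimator whenever
    observed frequencies touch the boundaries).  Errors only when the
    denominator vanishes entirely.
    """
    v = freqs[:-1] * (1 - freqs[:-1])
    if correction is not None:
        v = v * correction
    den = float(np.dot(dts, v))
    if den <= 0:
        raise MonomorphicTrajectoryError(
            "all retained time points are monomorphic (zero allele variance); "
            "the selection coefficient is not identifiable from these data"
        )
    num = freqs[-1] - freqs[0] - mu * np.dot(dts, 1 - 2 * freqs[:-1])
    return float(num), den


def s_mpl(freqs, dts, mu: float) -> float:
    """Closed-form MPL estimate from population (perfectly observed) frequencies."""
    freqs, dts = _check_lengths(freqs, dts)
    num, den = _numerator_denominator(freqs, dts, mu)
    return num / den


def s_mpl_batch(freqs: np.ndarray, dts, mu: float) -> np.ndarray:
    """Vectorized s_mpl over replicate trajectories (rows of ``freqs``).

    Matches :func:`s_mpl`'s term-dropping rule; replicates where every term
    vanishes yield NaN instead of raising.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    dts = np.asarray(dts, dtype=np.float64)
    v = freqs[:, :-1] * (1 - freqs[:, :-1])
    den = np.einsum("k,rk->r", dts, v)
    mut = np.einsum("k,rk->r", dts, 1 - 2 * freqs[:, :-1])
    num = freqs[:, -1] - freqs[:, 0] - mu * mut
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def s_hat(
    obs: ObservedTrajectory,
    mu: float,
    bias_correction: bool = True,
    N: int | None = None,
    ci_level: float | None = None,
) -> MPLEstimate:
    """Selection estimate from sampled counts, with variance bias correction.

    Parameters
    ----------
    obs : ObservedTrajectory
        Times, sample sizes, and mutant counts.
    mu : float
        Mutation probability per generation.
    bias_correction : bool
        Apply the per-time ``ns/(ns-1)`` factor to the sample variances
        (default).  Disable to reproduce the uncorrected plug-in estimator.
    N : int, optional
        Population size; required only when ``ci_level`` is given.
    ci_level : float, optional
        If set (e.g. 0.95), attach a likelihood-ratio confidence interval.
    """
    freqs = obs.freqs
    dts = obs.dts.astype(np.float64)
    corr = obs.sizes[:-1] / (obs.sizes[:-1] - 1) if bias_correction else None
    try:
        num, den = _numerator_denominator(freqs, dts, mu, correction=corr)
    except MonomorphicTrajectoryError:
        raise MonomorphicTrajectoryError(
            "uninformative observation: every retained sample is monomorphic"
        ) from None
    ci_low = ci_high = None
    if ci_level is not None:
        if N is None:
            raise ValueError("population size N is required for a confidence interval")
        ci_low, ci_high = likelihood_ratio_ci(freqs, dts, N, mu, level=ci_level)
    return MPLEstimate(
        s_hat=num / den,
        numerator=num,
        denominator=den,
        bias_corrected=bias_correction,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def s_hat_batch(
    counts: np.ndarray,
    sizes: np.ndarray,
    dts,
    mu: float,
    bias_correction: bool = True,
) -> np.ndarray:
    """Vectorized s_hat over replicate count matrices ``(n_reps, K+1)``.

    ``sizes`` is either a shared ``(K+1,)`` vector or per-replicate matrix.
    Undefined replicates (zero corrected integrated variance) yield NaN.
    """
    counts = np.asarray(counts, dtype=np.float64)
    sizes = np.asarray(sizes, dtype=np.float64)
    sizes = np.broadcast_to(sizes, counts.shape)
    freqs = counts / sizes
    dts = np.asarray(dts, dtype=np.float64)
    v = freqs[:, :-1] * (1 - freqs[:, :-1])
    if bias_correction:
        v = v * sizes[:, :-1] / (sizes[:, :-1] - 1)
    den = np.einsum("k,rk->r", dts, v)
    mut = np.einsum("k,rk->r", dts, 1 - 2 * freqs[:, :-1])
    num = freqs[:, -1] - freqs[:, 0] - mu * mut
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def log_likelihood(s: float, freqs, dts, N: int, mu: float) -> float:
    """Gaussian path log-likelihood of the frequency trajectory, up to the
    s-independent quantization constant.

    ``l(s) = sum_k [ 0.5 log(N / (2 pi dt_k v_k))
                     - (N/2) (x_{k+1} - x_k - dt_k (s v_k + mu (1-2 x_k)))^2
                       / (dt_k v_k) ]``

    Exactly quadratic in ``s`` with curvature ``-N sum_k dt_k v_k``.
    Zero-variance transitions are dropped with a warning (error if all are).
    """
    freqs, dts = _check_lengths(freqs, dts)
    v = freqs[:-1] * (1 - freqs[:-1])
    kept = v > 0
    if not kept.any():
        raise MonomorphicTrajectoryError(
            "all transitions start from a monomorphic frequency; the path "
            "likelihood is degenerate"
        )
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} zero-variance transition(s) from the "
            "path likelihood",
            RuntimeWarning,
            stacklevel=2,
        )
    v, dt = v[kept], dts[kept]
    x, x_next = freqs[:-1][kept], freqs[1:][kept]
    resid = x_next - x - dt * (s * v + mu * (1 - 2 * x))
    ll = 0.5 * np.log(N / (2 * np.pi * dt * v)) - (N / 2) * resid**2 / (dt * v)
    return float(ll.sum())


def likelihood_ratio_ci(
    freqs, dts, N: int, mu: float, level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval from the chi-square likelihood-ratio criterion.

    The set of ``s0`` with ``-2 [l(s0) - l(s^)] < chi2_1(level)`` (3.84 at
    95%).  Because the path log-likelihood is exactly quadratic in ``s``,
    the interval is ``s^ +/- sqrt(chi2_1(level) / (N * V_raw))`` where ``s^``
    is the likelihood argmax (the plug-in estimate without bias correction)
    and ``V_raw`` the uncorrected integrated sample variance over the
    retained terms.
    """
    freqs, dts = _check_lengths(freqs, dts)
    center = s_mpl(freqs, dts, mu)
    v = freqs[:-1] * (1 - freqs[:-1])
    v_raw = float(np.dot(dts, v))
    half = float(np.sqrt(chi2.ppf(level, df=1) / (N * v_raw)))
    return center - half, center + half
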