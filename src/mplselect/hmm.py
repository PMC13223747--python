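"""Benchmark HMM estimator modeling both genetic drift and limited sampling.

The frequency space [0, 1] is partitioned into D uniform bins (D = 100 by
default).  Hidden states are the bin midpoints of the population frequency;
transitions follow the Gaussian path-likelihood density of the MPL framework
evaluated between midpoints (rows renormalized to be stochastic), and
emissions are binomial: observing c mutants among ns samples given a
population frequency at midpoint m has probability Binom(c; ns, m).  The
estimate s_LS maximizes the forward-algorithm likelihood over s via
Nelder-Mead with tolerance 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import binom

from .evolve import ObservedTrajectory
from .mpl import MonomorphicTrajectoryError, s_hat

__all__ = ["FrequencyGrid", "HMMFit", "transition_matrix", "emission_prob",
           "hmm_loglik", "fit_s_ls"]


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform partition of [0, 1] into D bins with midpoints (i - 1/2)/D."""

    D: int = 100

    def __post_init__(self) -> None:
        if self.D < 2:
            raise ValueError("need at least two grid bins")

    @cached_property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.D + 1)

    @cached_property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.D) + 0.5) / self.D

    def bin_of(self, x: float) -> int:
        """Index of the bin containing frequency x (1.0 maps to the last bin)."""
        if not 0 <= x <= 1:
            raise ValueError("frequency must lie in [0, 1]")
        return min(int(x * self.D), self.D - 1)


@dataclass(frozen=True)
class HMMFit:
    """Result of the 1-D likelihood maximization."""

    s_ls: float
    loglik: float
    n_evals: int
    converged: bool


def _log_transition_matrix(
    grid: FrequencyGrid, s: float, mu: float, N: int, dt: float
) -> np.ndarray:
    m = grid.midpoints
    v = m * (1 - m)  # interior midpoints, so v > 0 for all rows
    drift = dt * (s * v + mu * (1 - 2 * m))
    resid = m[None, :] - (m + drift)[:, None]
    log_phi = -0.5 * N * resid**2 / (dt * v)[:, None]
    return log_phi - logsumexp(log_phi, axis=1, keepdims=True)


def transition_matrix(
    grid: FrequencyGrid, s: float, mu: float, N: int, dt: float
) -> np.ndarray:
    """Row-stochastic transition matrix between grid midpoints over dt generations.

    Entries are proportional to the Gaussian path-likelihood transition
    density between midpoints (drift ``dt (s v + mu (1-2m))``, variance
    ``dt v / N`` with ``v = m (1-m)``); each row is renormalized since the
    discretized density does not sum to one exactly.
    """
    return np.exp(_log_transition_matrix(grid, s, mu, N, dt))


def emission_prob(grid: FrequencyGrid, c: int, ns: int) -> np.ndarray:
    """Binomial emission vector: P(c | ns, m_i) for each grid midpoint."""
    if not 0 <= c <= ns:
        raise ValueError("count must lie in [0, ns]")
    return binom.pmf(c, ns, grid.midpoints)


def _initial_distribution(
    grid: FrequencyGrid,
    obs: ObservedTrajectory,
    init_prior: str,
    x0: float | None,
) -> np.ndarray:
    if init_prior == "point":
        pi = np.zeros(grid.D)
        pi[grid.bin_of(obs.freqs[0] if x0 is None else x0)] = 1.0
        return pi
    if init_prior == "uniform":
        return np.full(grid.D, 1.0 / grid.D)
    raise ValueError(f"unknown init_prior {init_prior!r}; expected 'point' or 'uniform'")


def _emission_matrix(grid: FrequencyGrid, obs: ObservedTrajectory) -> np.ndarray:
    """Emission probabilities for observations t_1..t_K, shape (K, D)."""
    return np.vstack(
        [emission_prob(grid, int(c), int(n)) for c, n in zip(obs.counts[1:], obs.sizes[1:])]
    )


def _forward_loglik(
    pi: np.ndarray,
    emissions: np.ndarray,
    dts: np.ndarray,
    grid: FrequencyGrid,
    s: float,
    mu: float,
    N: int,
) -> float:
    """Scaled forward recursion; renormalizing each step avoids underflow."""
    trans_cache: dict[float, np.ndarray] = {}
    alpha = pi
    loglik = 0.0
    for k, dt in enumerate(dts):
        dt = float(dt)
        if dt not in trans_cache:
            trans_cache[dt] = transition_matrix(grid, s, mu, N, dt)
        alpha = (alpha @ trans_cache[dt]) * emissions[k]
        z = alpha.sum()
        if z <= 0:
            return -np.inf
        loglik += np.log(z)
        alpha = alpha / z
    return float(loglik)


def hmm_loglik(
    s: float,
    obs: ObservedTrajectory,
    N: int,
    mu: float,
    grid: FrequencyGrid | None = None,
    init_prior: str = "point",
    x0: float | None = None,
) -> float:
    """Forward-algorithm log-likelihood of the observed counts given s.

    Conditions on the initial frequency via a point mass: on the bin of the
    known population frequency ``x0`` when given (the likelihood is defined
    conditional on x(t_0)), otherwise on the bin of the observed x^(t_0);
    ``init_prior='uniform'`` spreads the prior instead.  Emissions apply at
    times t_1..t_K.  The forward recursion is renormalized at every step, so
    it cannot underflow.  Heterogeneous sampling steps are supported by
    rebuilding the transition matrix per distinct dt.
    """
    if len(obs) < 2:
        raise ValueError("need at least two observation times")
    if grid is None:
        grid = FrequencyGrid()
    pi = _initial_distribution(grid, obs, init_prior, x0)
    return _forward_loglik(pi, _emission_matrix(grid, obs), obs.dts, grid, s, mu, N)


def fit_s_ls(
    obs: ObservedTrajectory,
    N: int,
    mu: float,
    grid: FrequencyGrid | None = None,
    init_s: float | None = None,
    tol: float = 1e-4,
    init_prior: str = "point",
    x0: float | None = None,
) -> HMMFit:
    """Maximum-likelihood s from the drift + sampling HMM (Nelder-Mead, 1-D).

    The simplex is initialized at the closed-form estimate of the observed
    data when available (it sits near the optimum), falling back to 0; both
    the simplex x- and f-tolerances are ``tol``.  ``x0`` is the known initial
    population frequency, when available (see :func:`hmm_loglik`).
    """
    if len(obs) < 2:
        raise ValueError("need at least two observation times")
    if grid is None:
        grid = FrequencyGrid()
    if init_s is None:
        try:
            init_s = s_hat(obs, mu).s_hat
        except MonomorphicTrajectoryError:
            init_s = 0.0

    pi = _initial_distribution(grid, obs, init_prior, x0)
    emissions = _emission_matrix(grid, obs)

    def neg_loglik(sv: np.ndarray) -> float:
        return -_forward_loglik(pi, emissions, obs.dts, grid, float(sv[0]), mu, N)

    res = minimize(
        neg_loglik,
        x0=[init_s],
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol},
    )
    return HMMFit(
        s_ls=float(res.x[0]),
        loglik=-float(res.fun),
        n_evals=int(res.nfev),
        converged=bool(res.success),
    )
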