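"""Single-locus evolution simulators and limited-sampling observation.

Implements the Wright-Fisher (WF) model with selection and mutation, its
infinite-population deterministic analogues (exact and linearized one-step
recursions), and binomial sampling of population frequencies at a set of
observation times.  These simulators are the synthetic-data backbone for
studying selection-coefficient estimators: the WF model contributes genetic
drift, the observation step contributes limited-sampling noise, and the
deterministic models isolate the latter.

Conventions
-----------
* Haploid population of ``N`` individuals; the mutant allele has Wrightian
  fitness ``1 + s``; mutation is symmetric with per-generation probability
  ``mu``.
* WF state is stored internally as an integer mutant count ``n(t)`` and
  exposed as the frequency ``x(t) = n(t) / N``, so trajectories never
  accumulate float drift.
* All randomness flows through :class:`numpy.random.Generator`; ensemble
  helpers draw vectorized, time-major (one call per generation across all
  replicates), so a fixed seed reproduces results bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EvolutionParams",
    "SamplingDesign",
    "Trajectory",
    "ObservedTrajectory",
    "wf_success_prob",
    "wf_step",
    "det_step",
    "simulate",
    "wf_ensemble",
    "observe",
    "observe_counts",
]

MODEL_TAGS = ("wf", "det_exact", "det_linear")


@dataclass(frozen=True)
class EvolutionParams:
    """Parameterization of the single-locus evolutionary model.

    Parameters
    ----------
    N : int
        Population size (number of haploid individuals), >= 2.
    s : float
        Selection coefficient; mutant Wrightian fitness is ``1 + s``.
    mu : float
        Symmetric per-generation mutation probability, >= 0.
    x0 : float
        Initial mutant allele frequency in [0, 1].
    """

    N: int
    s: float
    mu: float
    x0: float

    def __post_init__(self) -> None:
        if self.N < 2 or int(self.N) != self.N:
            raise ValueError(f"population size N must be an integer >= 2, got {self.N}")
        if 1 + self.s <= 0:
            raise ValueError(f"mutant fitness 1+s must be positive, got s={self.s}")
        if self.mu < 0:
            raise ValueError(f"mutation probability must be >= 0, got {self.mu}")
        if not 0 <= self.x0 <= 1:
            raise ValueError(f"initial frequency x0 must lie in [0, 1], got {self.x0}")


@dataclass(frozen=True)
class SamplingDesign:
    """Observation schedule: when and how many individuals are sampled.

    Exactly one of ``ns`` (fixed size, or one size per time point) and
    ``ns_mean`` (Poisson-distributed time-varying sizes) must be given.
    Poisson draws below 2 are redrawn, since a sample of size 0 or 1 carries
    no variance information and breaks the ``ns/(ns-1)`` bias correction.
    """

    times: tuple[int, ...]
    ns: int | tuple[int, ...] | None = None
    ns_mean: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        times = tuple(int(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if len(times) < 2:
            raise ValueError("need at least two sampling times (K >= 1 intervals)")
        if any(b - a < 1 for a, b in zip(times, times[1:])):
            raise ValueError("sampling times must be strictly increasing integers")
        if (self.ns is None) == (self.ns_mean is None):
            raise ValueError("specify exactly one of ns and ns_mean")
        if self.ns is not None:
            ns = self.ns
            if np.isscalar(ns):
                ns = (int(ns),) * len(times)
            else:
                ns = tuple(int(n) for n in ns)
                if len(ns) != len(times):
                    raise ValueError("per-time ns must match the number of sampling times")
            if any(n < 2 for n in ns):
                raise ValueError("every sample size must be >= 2")
            object.__setattr__(self, "ns", ns)
        elif self.ns_mean <= 0:
            raise ValueError("Poisson mean sample size must be positive")

    @classmethod
    def regular(
        cls,
        dt: int,
        T: int,
        ns: int | Sequence[int] | None = None,
        ns_mean: float | None = None,
        seed: int | None = None,
    ) -> "SamplingDesign":
        """Design with times 0, dt, 2*dt, ..., T (T must be a multiple of dt)."""
        if T % dt != 0:
            raise ValueError(f"T={T} is not a multiple of dt={dt}")
        return cls(times=tuple(range(0, T + 1, dt)), ns=ns, ns_mean=ns_mean, seed=seed)

    @property
    def dts(self) -> np.ndarray:
        t = np.asarray(self.times)
        return np.diff(t)

    def realize_sizes(self, rng: np.random.Generator) -> np.ndarray:
        """Sample sizes at each time point (draws Poisson sizes if needed)."""
        if self.ns is not None:
            return np.asarray(self.ns, dtype=np.int64)
        sizes = rng.poisson(self.ns_mean, size=len(self.times))
        while (small := sizes < 2).any():  # redraw degenerate sizes
            sizes[small] = rng.poisson(self.ns_mean, size=int(small.sum()))
        return sizes.astype(np.int64)


@dataclass(frozen=True)
class Trajectory:
    """Population mutant allele frequencies x(t) at a set of generations."""

    times: np.ndarray
    freqs: np.ndarray
    model_tag: str = "wf"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.int64)
        freqs = np.asarray(self.freqs, dtype=np.float64)
        if times.shape != freqs.shape or times.ndim != 1:
            raise ValueError("times and freqs must be 1-D arrays of equal length")
        if ((freqs < 0) | (freqs > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        if self.model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {self.model_tag!r}; expected one of {MODEL_TAGS}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "freqs", freqs)

    def at(self, times: Sequence[int]) -> np.ndarray:
        """Frequencies at the requested generations (error if any is missing)."""
        idx = {int(t): i for i, t in enumerate(self.times)}
        try:
            return self.freqs[[idx[int(t)] for t in times]]
        except KeyError as e:
            raise ValueError(f"generation {e.args[0]} not present in the trajectory") from None

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ObservedTrajectory:
    """Binomially sampled allele counts at the observation times."""

    times: np.ndarray
    sizes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.int64)
        sizes = np.asarray(self.sizes, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if not (times.shape == sizes.shape == counts.shape) or times.ndim != 1:
            raise ValueError("times, sizes, counts must be 1-D arrays of equal length")
        if len(times) >= 2 and (np.diff(times) < 1).any():
            raise ValueError("observation times must be strictly increasing")
        if (sizes < 2).any():
            raise ValueError("sample sizes must be >= 2")
        if ((counts < 0) | (counts > sizes)).any():
            raise ValueError("mutant counts must lie in [0, sample size]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "counts", counts)

    @property
    def freqs(self) -> np.ndarray:
        """Observed frequencies x^(t_k) = c(t_k) / ns(t_k)."""
        return self.counts / self.sizes

    @property
    def dts(self) -> np.ndarray:
        return np.diff(self.times)

    def __len__(self) -> int:
        return len(self.times)


def wf_success_prob(x, s: float, mu: float):
    """Expected offspring mutant fraction p(t) under selection and mutation.

    ``p = [(1+s) x + mu ((1-x) - (1+s) x)] / (1 + s x)``; the WF offspring
    count is Binomial(N, p).  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=np.float64)
    if ((x < 0) | (x > 1)).any():
        raise ValueError("frequency x must lie in [0, 1]")
    sel = (1 + s) * x
    p = (sel + mu * ((1 - x) - sel)) / (1 + s * x)
    # guard against float round-off pushing p marginally outside [0, 1]
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


def wf_step(x, params: EvolutionParams, rng: np.random.Generator):
    """One WF generation: binomial resampling of N offspring. Vectorized in x."""
    p = wf_success_prob(x, params.s, params.mu)
    draw = rng.binomial(params.N, p) / params.N
    return float(draw) if np.ndim(x) == 0 else draw


def det_step(x, s: float, mu: float, variant: str = "exact"):
    """One generation of the infinite-population (deterministic) model.

    ``exact`` applies the full selection-mutation recursion
    ``x' = [mu (1-x) + (1+s)(1-mu) x] / (1 + s x)``; ``linear`` applies its
    first-order expansion ``x' = x + s v + mu (1 - 2x)`` with
    ``v = x (1-x)``, clipped to [0, 1] (with a warning) since the linearized
    update can overshoot the boundaries for extreme parameters.
    """
    x = np.asarray(x, dtype=np.float64)
    if ((x < 0) | (x > 1)).any():
        raise ValueError("frequency x must lie in [0, 1]")
    if variant == "exact":
        out = (mu * (1 - x) + (1 + s) * (1 - mu) * x) / (1 + s * x)
        out = np.clip(out, 0.0, 1.0)  # round-off only; the map preserves [0, 1]
    elif variant == "linear":
        out = x + s * x * (1 - x) + mu * (1 - 2 * x)
        if ((out < 0) | (out > 1)).any():
            warnings.warn(
                "linearized deterministic update left [0, 1]; clipping",
                RuntimeWarning,
                stacklevel=2,
            )
            out = np.clip(out, 0.0, 1.0)
    else:
        raise ValueError(f"unknown variant {variant!r}; expected 'exact' or 'linear'")
    return out if out.ndim else float(out)


def simulate(
    params: EvolutionParams,
    T: int,
    model: str = "wf",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate a trajectory of T generations (length T+1, starting at x0).

    Deterministic models ignore the seed; the WF model is reproducible given
    one.  ``model`` is one of ``wf``, ``det_exact``, ``det_linear``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if model not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model!r}; expected one of {MODEL_TAGS}")
    times = np.arange(T + 1)
    freqs = np.empty(T + 1)
    if model == "wf":
        if rng is None:
            rng = np.random.default_rng(seed)
        n = round(params.x0 * params.N)  # integer state avoids float drift
        freqs[0] = n / params.N
        for t in range(T):
            p = wf_success_prob(n / params.N, params.s, params.mu)
            n = rng.binomial(params.N, p)
            freqs[t + 1] = n / params.N
    else:
        variant = "exact" if model == "det_exact" else "linear"
        x = params.x0
        freqs[0] = x
        for t in range(T):
            x = det_step(x, params.s, params.mu, variant=variant)
            freqs[t + 1] = x
    return Trajectory(times=times, freqs=freqs, model_tag=model)


def wf_ensemble(
    params: EvolutionParams,
    T: int,
    n_reps: int,
    rng: np.random.Generator,
    record_times: Sequence[int] | None = None,
) -> np.ndarray:
    """Simulate ``n_reps`` WF trajectories at once.

    Returns an array of shape ``(n_reps, len(record_times))`` of frequencies
    (all generations 0..T if ``record_times`` is None).  Draws are time-major:
    one vectorized binomial per generation across replicates.
    """
    if record_times is None:
        record_times = np.arange(T + 1)
    record_times = np.asarray(record_times, dtype=np.int64)
    if record_times.max() > T or record_times.min() < 0:
        raise ValueError("record_times must lie in [0, T]")
    keep = np.full(T + 1, -1, dtype=np.int64)
    keep[record_times] = np.arange(len(record_times))

    out = np.empty((n_reps, len(record_times)))
    n = np.full(n_reps, round(params.x0 * params.N), dtype=np.int64)
    if keep[0] >= 0:
        out[:, keep[0]] = n / params.N
    for t in range(1, T + 1):
        p = wf_success_prob(n / params.N, params.s, params.mu)
        n = rng.binomial(params.N, p)
        if keep[t] >= 0:
            out[:, keep[t]] = n / params.N
    return out


def observe(
    traj: Trajectory,
    design: SamplingDesign,
    rng: np.random.Generator | None = None,
) -> ObservedTrajectory:
    """Draw binomial samples of the population at the design's time points.

    ``c(t_k) ~ Binomial(ns(t_k), x(t_k))`` independently at each time; the
    binomial model is used even when ``ns`` approaches N (sampling with
    replacement, as assumed throughout).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    x = traj.at(design.times)
    sizes = design.realize_sizes(rng)
    counts = rng.binomial(sizes, x)
    return ObservedTrajectory(times=np.asarray(design.times), sizes=sizes, counts=counts)


def observe_counts(
    freqs: np.ndarray,
    sizes: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized observation: ``n_reps`` independent count vectors.

    ``freqs`` may be a single trajectory ``(K+1,)`` (each replicate observes
    the same population trajectory) or per-replicate ``(n_reps, K+1)``.
    Returns counts of shape ``(n_reps, K+1)``.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    sizes = np.asarray(sizes, dtype=np.int64)
    if freqs.ndim == 1:
        freqs = np.broadcast_to(freqs, (n_reps, len(freqs)))
    elif freqs.shape[0] != n_reps:
        raise ValueError("per-replicate freqs must have n_reps rows")
    return rng.binomial(sizes[None, :], freqs)
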