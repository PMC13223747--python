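"""TSV input/output, the diploid-codominant adapter, and experiment sweeps.

File formats (UTF-8, tab-separated, header required, generations are
non-negative integers):

* trajectory: ``generation<TAB>frequency``
* observations: ``generation<TAB>sample_size<TAB>mutant_count``

Real datasets recorded in calendar years (one generation per year) should be
mapped to generations as ``year - first_year`` before writing the TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import theory
from .evolve import EvolutionParams, ObservedTrajectory, SamplingDesign, Trajectory

__all__ = [
    "read_trajectory_tsv",
    "write_trajectory_tsv",
    "read_observed_tsv",
    "write_observed_tsv",
    "diploid_adapter",
    "ExperimentConfig",
    "run_experiment",
]

logger = logging.getLogger("mplselect")

TRAJ_COLUMNS = ["generation", "frequency"]
OBS_COLUMNS = ["generation", "sample_size", "mutant_count"]
CONFIG_SCHEMA_VERSION = 1


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if list(df.columns) != columns:
        raise ValueError(f"{path}: expected header {columns}, found {list(df.columns)}")
    if df.isna().any().any():
        bad = int(df[df.isna().any(axis=1)].index[0]) + 2  # +2: header + 1-based
        raise ValueError(f"{path}: malformed row at line {bad}")
    if df["generation"].duplicated().any():
        dup = int(df.loc[df["generation"].duplicated(), "generation"].iloc[0])
        raise ValueError(f"{path}: duplicate generation {dup}")
    if (df["generation"] < 0).any() or (df["generation"] % 1 != 0).any():
        raise ValueError(f"{path}: generations must be non-negative integers")
    if not df["generation"].is_monotonic_increasing:
        raise ValueError(f"{path}: rows must be sorted by generation")
    return df


def read_trajectory_tsv(path, model_tag: str = "wf") -> Trajectory:
    """Load a population-frequency trajectory from TSV."""
    df = _read_tsv(path, TRAJ_COLUMNS)
    return Trajectory(
        times=df["generation"].to_numpy(np.int64),
        freqs=df["frequency"].to_numpy(np.float64),
        model_tag=model_tag,
    )


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    pd.DataFrame({"generation": traj.times, "frequency": traj.freqs}).to_csv(
        path, sep="\t", index=False
    )


def read_observed_tsv(path) -> ObservedTrajectory:
    """Load observed counts from TSV (validates counts <= sizes, sizes >= 2)."""
    df = _read_tsv(path, OBS_COLUMNS)
    return ObservedTrajectory(
        times=df["generation"].to_numpy(np.int64),
        sizes=df["sample_size"].to_numpy(np.int64),
        counts=df["mutant_count"].to_numpy(np.int64),
    )


def write_observed_tsv(obs: ObservedTrajectory, path) -> None:
    pd.DataFrame(
        {"generation": obs.times, "sample_size": obs.sizes, "mutant_count": obs.counts}
    ).to_csv(path, sep="\t", index=False)


def diploid_adapter(obs: ObservedTrajectory, twoN: int) -> tuple[ObservedTrajectory, int]:
    """Codominant-diploid convention: analyze allele counts on 2N gametes.

    With genotype fitnesses 1, 1+s, 1+2s (additive), allele-frequency
    dynamics in a diploid population of N individuals match the haploid
    model on 2N gametes.  Input counts must already be *allele* counts
    (sample sizes counted in alleles); the data pass through unchanged and
    the effective population size for inference is ``twoN``.
    """
    if twoN < 2:
        raise ValueError("2N must be >= 2")
    return obs, int(twoN)


@dataclass(frozen=True)
class ExperimentConfig:
    """Sweep specification: one Monte-Carlo summary per (T, ns, dt) combination.

    ``statistic`` selects which noise sources the replicates include:
    ``joint`` (WF + sampling), ``sampling`` (fixed mean trajectory), or
    ``drift`` (WF with perfect sampling).
    """

    N: int
    s: float
    mu: float
    x0: float
    T_values: tuple[int, ...]
    ns_values: tuple[int, ...]
    dt_values: tuple[int, ...]
    n_reps: int
    seed: int
    statistic: str = "joint"
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {self.schema_version}")
        if self.statistic not in ("joint", "sampling", "drift"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        for name in ("T_values", "ns_values", "dt_values"):
            object.__setattr__(self, name, tuple(int(v) for v in getattr(self, name)))
        # fail fast on invalid evolutionary parameters
        EvolutionParams(N=self.N, s=self.s, mu=self.mu, x0=self.x0)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_experiment(config: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Run the configured sweep; one row of Monte-Carlo moments per setting.

    Each setting gets an independent RNG stream spawned deterministically
    from the config seed, so the sweep is reproducible and rerunning with
    the same config is bit-identical.  Writes ``results.tsv`` and a log file
    under ``out_dir`` when given.
    """
    params = EvolutionParams(N=config.N, s=config.s, mu=config.mu, x0=config.x0)
    settings = [
        (T, ns, dt)
        for T in config.T_values
        for ns in config.ns_values
        for dt in config.dt_values
        if T % dt == 0
    ]
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(settings))
    rows = []
    for (T, ns, dt), child in zip(settings, children):
        seed = int(child.generate_state(1)[0] % (2**31))
        design = SamplingDesign.regular(dt=dt, T=T, ns=ns)
        if config.statistic == "joint":
            summ = theory.joint_variance_empirical(params, design, config.n_reps, seed)
        elif config.statistic == "sampling":
            summ = theory.sampling_only_variance_empirical(params, design, config.n_reps, seed)
        else:
            summ = theory.drift_only_variance_empirical(
                params, np.asarray(design.times), config.n_reps, seed
            )
        rows.append(
            {
                "T": T,
                "ns": ns,
                "dt": dt,
                "n_reps": summ.n_reps,
                "n_failed": summ.n_failed,
                "mean": summ.mean,
                "variance": summ.variance,
                "se_mean": summ.se_mean,
                "se_var": summ.se_var,
            }
        )
        logger.info("setting T=%d ns=%d dt=%d done (n_failed=%d)", T, ns, dt, summ.n_failed)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "results.tsv", sep="\t", index=False)
        meta = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        }
        (out_dir / "run.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return df
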