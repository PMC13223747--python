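import numpy as np
import pytest

from mplselect import EvolutionParams, SamplingDesign, simulate


@pytest.fixture(scope="session")
def study_params() -> EvolutionParams:
    """The reference study conditions: N=1000, s=0.02, mu=1e-3, x0=0.1."""
    return EvolutionParams(N=1000, s=0.02, mu=1e-3, x0=0.1)


@pytest.fixture(scope="session")
def study_design() -> SamplingDesign:
    """Reference sampling design: every 10 generations over T=450, ns=20."""
    return SamplingDesign.regular(dt=10, T=450, ns=20)


@pytest.fixture(scope="session")
def det_trajectory(study_params):
    """Exact deterministic trajectory over 450 generations."""
    return simulate(study_params, 450, model="det_exact")


@pytest.fixture(scope="session")
def det_sampled(det_trajectory, study_design):
    """(freqs at design times, dts) for the reference trajectory."""
    x = det_trajectory.at(study_design.times)
    return x, study_design.dts.astype(float)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
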