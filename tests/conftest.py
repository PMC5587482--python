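import numpy as np
import pytest

from coevoscan.sim_core import CoevArchitecture, SimParams, run_simulation


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_metapop():
    """A small but non-trivial simulated metapopulation (discrete model)."""
    params = SimParams(
        n_pops=8,
        n_loci_host=24,
        n_loci_par=24,
        n_coev=2,
        model="discrete_matching",
        beta=0.9,
        s=0.8,
        eta_host=60,
        eta_par=60,
        mu_host=0.03,
        mu_par=0.03,
        m_host=0.002,
        m_par=0.002,
        r_host=0.3,
        r_par=0.3,
        generations=60,
        seed=99,
    )
    return run_simulation(params)


@pytest.fixture
def arch_1locus():
    return CoevArchitecture.from_indices([3], [5], "discrete_matching")
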