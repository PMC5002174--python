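import numpy as np
import pytest
from hypothesis import settings

from nbmmseq import SimulationDesign, simulate_dataset, simulate_gene
from nbmmseq.nbmm import FitOptions
from nbmmseq.simulate import eta_mean

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


#: frozen hyperparameters and dispersion: single inner fit per model, used
#: where the test exercises machinery other than the selection itself
FAST_OPTIONS = FitOptions().frozen(1e-2, 1.0, 1.0, 1000.0)


@pytest.fixture(scope="session")
def linear_sim():
    """Scenario-1 linear study (25 DE + 25 NDE, 3 replicates)."""
    return simulate_dataset(
        SimulationDesign(setting="linear", scenario=1, replicates=3, seed=0)
    )


@pytest.fixture(scope="session")
def cyclic_sim():
    return simulate_dataset(
        SimulationDesign(setting="cyclic", scenario=1, replicates=3, seed=0)
    )


@pytest.fixture(scope="session")
def de_gene(linear_sim):
    return linear_sim.datasets[0]


@pytest.fixture(scope="session")
def nde_gene(linear_sim):
    return linear_sim.datasets[30]


@pytest.fixture
def fast_options():
    return FAST_OPTIONS


def make_gene(setting="linear", de=True, replicates=3, seed=0, nu=1000.0,
              sigma_b=1.0, C=2.0, gene_id="gene"):
    """One simulated gene outside the standard scenario layouts."""
    design = SimulationDesign(
        setting=setting, replicates=replicates, nu=nu, sigma_b=sigma_b, C=C
    )
    rng = np.random.default_rng(seed)
    fn = lambda t, g: eta_mean(setting, t, g, C=C, de=de)
    return simulate_gene(fn, design, rng, gene_id)
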