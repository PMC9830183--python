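import numpy as np
import pytest

import socortex as sc


@pytest.fixture(scope="session")
def small_sim():
    """A compact 6-species dataset with planted toolkit and modules."""
    cfg = sc.SimulationConfig(
        n_genes=120,
        n_toolkit_genes=12,
        n_clade_specific_genes=6,
        n_modules=2,
        module_size_range=(12, 18),
        n_trait_modules=1,
        toolkit_lfc=1.5,
        n_samples_per_phenotype={sp: (6, 6) for sp in sc.SimulationConfig().species},
        seed=7,
    )
    dataset, truth = sc.simulate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def small_vst(small_sim):
    _, dataset, _ = small_sim
    return sc.variance_stabilize(dataset, species_aware=True)


@pytest.fixture(scope="session")
def small_scaled(small_sim, small_vst):
    _, dataset, _ = small_sim
    return sc.center_scale(small_vst, scope="per_species", metadata=dataset.samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
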