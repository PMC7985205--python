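import numpy as np
import pytest

from tissueoptics import (
    MomentInversion,
    OpticalProperties,
    SimulationConfig,
    SlabGeometry,
    generate_dataset,
    run_simulation,
    split_dataset,
)


@pytest.fixture(scope="session")
def baseline_props() -> OpticalProperties:
    """Realistic tissue slab: n=1.4, g=0.85, mu_s'=1 mm^-1, mu_a=0.1 mm^-1."""
    return OpticalProperties.from_reduced(n=1.4, g=0.85, mu_s_prime=1.0, mu_a=0.1)


@pytest.fixture(scope="session")
def small_result(baseline_props):
    """One modest baseline run shared by featurization tests."""
    return run_simulation(
        baseline_props, SlabGeometry(), SimulationConfig(n_photons=20_000, seed=11)
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """30 fast low-photon runs over the full parameter ranges, 10 held out."""
    ds = generate_dataset(
        n_runs=30, sim_config=SimulationConfig(n_photons=2_000), master_seed=3
    )
    return split_dataset(ds, n_test=10, seed=3)


@pytest.fixture(scope="session")
def micro_memorized(tiny_dataset):
    """Tiny model driven to memorize its training split (lbfgs)."""
    model = MomentInversion.from_dataset(tiny_dataset, split="train")
    return model.fit(hidden_size=150, epochs=3000, seed=0, solver="lbfgs")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
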