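import pytest

from dualtap.design import StudyDesign, build_sample_records
from dualtap.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def samples(design):
    return build_sample_records(design)


@pytest.fixture(scope="session")
def default_dataset(design, samples):
    """One full-size simulated dataset (seed 1, study defaults)."""
    return generate_dataset(design, SimulationConfig(seed=1), samples)


@pytest.fixture(scope="session")
def small_design():
    """A reduced layout for fast end-to-end tests (2 couples x 2 replicates)."""
    return StudyDesign(n_couples=2, replicates_per_arm=2)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_background=40,
        n_cross_reactive_per_tag=5,
        n_core=3,
        n_ha_specific=5,
        n_v5_specific=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design, small_config):
    samples = build_sample_records(small_design)
    peptides, truth = generate_dataset(small_design, small_config, samples)
    return samples, peptides, truth
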