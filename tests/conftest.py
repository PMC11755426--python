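import numpy as np
import pytest

from mnrm import SimulationDesign, assemble_item_weights, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_weight_set():
    """Two traits, three items each, 7 categories, all style dimensions."""
    item_map = {f"it{i}": i // 3 for i in range(6)}
    fw = {f"it{i}": np.linspace(0, 1, 7) for i in range(6)}
    return assemble_item_weights(item_map, 2, 7, faking_weights=fw)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small simulated dataset reused by estimation and IO tests."""
    design = SimulationDesign(
        n_traits=2,
        items_per_trait=4,
        sample_sizes=(120,),
        faking_present=True,
        faking_trait_corr=(0.2, -0.2),
    )
    return generate_dataset(design, 1234, n=120)
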