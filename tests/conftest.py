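import numpy as np
import pandas as pd
import pytest

from subelim.population import CellPopulation, PopulationConfig, make_population


@pytest.fixture(scope="session")
def small_population() -> CellPopulation:
    """A modest culture with the default mixture and marker profiles."""
    return make_population(PopulationConfig.from_neurons(1200), seed=11)


@pytest.fixture()
def two_class_profiles() -> pd.DataFrame:
    """One background gene everywhere, one subgroup-exclusive marker."""
    return pd.DataFrame(
        {
            "trpv1_pos_neuron": [100.0, 50.0],
            "trpv1_neg_small_neuron": [100.0, 0.0],
            "nf200_large_neuron": [100.0, 0.0],
            "non_neuronal": [100.0, 0.0],
        },
        index=["bg", "marker"],
    )
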