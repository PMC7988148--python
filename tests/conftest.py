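import numpy as np
import pytest

from recat.simulate import Simulation, small_config


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """One scaled-down simulation shared by read-only tests."""
    return Simulation(small_config(seed=11))


@pytest.fixture(scope="session")
def small_sim_products(small_sim):
    """Expensive products of the shared simulation, generated once."""
    genome, peaks, pwm = small_sim.ctcf_architecture()
    genes_df, res_df = small_sim.expression_and_signal()
    return {
        "genome": genome,
        "peaks": peaks,
        "pwm": pwm,
        "gene_counts": genes_df,
        "re_counts": res_df,
    }
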