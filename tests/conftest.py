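import pytest
from hypothesis import HealthCheck, settings

from degnet.synthetic import SimConfig, simulate_all

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A desk-scale study configuration shared across tests.

    2,000 genes keep every stage fast while leaving room for 100 planted
    differential genes, four 15-gene GO modules and 20 prenatal-peak genes.
    """
    return SimConfig(
        n_genes=2000,
        ppi_n_edges=4000,
        module_sizes=(15, 15, 15, 15),
        n_background_terms=10,
        n_prenatal_max=20,
        seed=1,
    )


@pytest.fixture(scope="session")
def bundle(small_config):
    return simulate_all(small_config)
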