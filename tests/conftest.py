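import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_config():
    from reefdisparity.simulate import SimulationConfig

    return SimulationConfig(
        n_species=6,
        family_sizes=(2, 2, 1, 1),
        n_locations=3,
        individuals_per_location=8,
        n_loci=60,
        n_per_pop=8,
        inter_species_per_genus=2,
        inter_genera_per_family=2,
        coupling=0.5,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    from reefdisparity.simulate import simulate_study

    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    from reefdisparity.simulate import simulate_study

    out = tmp_path_factory.mktemp("bundle")
    simulate_study(small_config, out_dir=out, overwrite=True)
    return out
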