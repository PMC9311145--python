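import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Preset experiment with noise switched off (exact recovery expected)."""
    from plfasip import paper_like_preset, simulate_experiment

    cfg = paper_like_preset(seed=11, noise_sd_conc=0.0, noise_sd_delta=0.0)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noiseless_partition(noiseless_experiment):
    from plfasip import partition_experiment

    sim = noiseless_experiment
    return partition_experiment(sim.measurements, sim.designs, sim.config.constants())


@pytest.fixture(scope="session")
def noisy_experiment():
    """Preset experiment at the default instrument-noise level."""
    from plfasip import paper_like_preset, simulate_experiment

    return simulate_experiment(paper_like_preset(seed=23))
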