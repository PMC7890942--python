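import pytest
from hypothesis import HealthCheck, settings

from svsweep import CallerProfile, SimulationConfig, simulate_callsets, simulate_truth

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def noiseless_callers(n: int = 3, genotyping: bool = True) -> tuple[CallerProfile, ...]:
    names = ("delly", "manta", "genomestrip", "breakdancer", "pindel", "cnvnator")
    return tuple(
        CallerProfile(name, fnr=0.0, fpr_per_mb=0.0, jitter_sd=0.0,
                      genotyping=genotyping, genotype_error=0.0)
        for name in names[:n]
    )


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7,
        n_sites={"DEL": 120, "INS": 15, "INV": 4, "DUP": 6, "TRA": 3},
        populations=(("MS", 10), ("DU", 10), ("TB", 10)),
        callers=noiseless_callers(3),
    )


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_config):
    return simulate_truth(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_callsets(noiseless_truth):
    return simulate_callsets(noiseless_truth)
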