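import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microvarsig.simulate import (
    ClusterPlan,
    GroupSpec,
    SimConfig,
    simulate_genomes,
    simulate_variant_sets,
)

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but fully featured cohort: 2 planted clusters, paired
    day0/day30 samples, one family per selection regime."""
    cfg = SimConfig(
        seed=7,
        n_genomes=3,
        genome_length=20_000,
        n_genes_per_genome=25,
        n_marker_genes=10,
        groups=[GroupSpec("FU", "day0", 3), GroupSpec("FU", "day30", 3)],
        cluster_plan=ClusterPlan(sizes=[2, 1]),
        omega_map={"K00001": 0.1, "K00002": 1.0, "K00003": 5.0},
        n_codons_per_family=60,
        n_seqs_per_family=6,
    )
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_genomes(small_config):
    return simulate_genomes(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_genomes):
    calls, truth, meta = simulate_variant_sets(small_genomes, small_config)
    return calls, truth, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
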