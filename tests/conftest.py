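import pytest
from hypothesis import HealthCheck, settings

import polyhist as ph

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return ph.SimConfig(n_genes=4, contig_length=4000, depth_per_condition=400,
                        polyA_fraction=0.1, effect_size=4.0, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    genome, models, truth = ph.make_toy_genome(small_config)
    return genome, models, truth


@pytest.fixture(scope="session")
def fixture_config():
    """The bundled study-scale fixture: 20 genes, 10k reads per condition."""
    return ph.SimConfig(seed=11)


@pytest.fixture(scope="session")
def fixture_sim(fixture_config):
    genome, models, truth = ph.make_toy_genome(fixture_config)
    return genome, models, truth


@pytest.fixture(scope="session")
def fixture_libraries(fixture_config, fixture_sim):
    """Simulated error-free reads for both conditions of the bundled fixture."""
    genome, models, truth = fixture_sim
    libs = {}
    for cond in fixture_config.conditions:
        reads, sidecar = ph.simulate_aseq_reads(genome, models, truth, cond,
                                                fixture_config)
        libs[cond] = (reads, sidecar)
    return libs


@pytest.fixture(scope="session")
def fixture_site_tables(fixture_sim, fixture_libraries):
    genome, models, _ = fixture_sim
    tables, stats = {}, {}
    for cond, (reads, _) in fixture_libraries.items():
        table, st = ph.call_library([r.sequence for r in reads], genome)
        ph.assign_sites_to_genes(table, models)
        tables[cond] = table
        stats[cond] = st
    return tables, stats
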