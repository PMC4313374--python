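"""Shared fixtures: deterministic synthetic genomes and the built-in templates."""

import pytest
from hypothesis import HealthCheck, settings

from trypanotag import FixtureSpec, get_template, load_genome, make_genome

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ppotv4():
    return get_template("pPOTv4")


@pytest.fixture(scope="session")
def ppotv2():
    return get_template("pPOTv2")


@pytest.fixture(scope="session")
def plent_yb():
    return get_template("pLENTv2-YB")


@pytest.fixture(scope="session")
def genome_paths(tmp_path_factory):
    """A 22-gene genome with both strands represented."""
    spec = FixtureSpec(n_genes=22, seed=7, strand_mix=0.5)
    return make_genome(spec, tmp_path_factory.mktemp("genome"))


@pytest.fixture(scope="session")
def genome(genome_paths):
    return load_genome(genome_paths["fasta"], genome_paths["gff3"])


@pytest.fixture(scope="session")
def paralog_genome(tmp_path_factory):
    """Three genes plus a 95%-identity paralog of the first (off-target bait)."""
    spec = FixtureSpec(
        n_genes=3,
        seed=13,
        strand_mix=0.0,
        paralog_specs=[(0, 0.95)],
        intergenic_length_range=(1200, 1500),
    )
    paths = make_genome(spec, tmp_path_factory.mktemp("paralog"))
    return load_genome(paths["fasta"], paths["gff3"])


@pytest.fixture()
def gene(genome):
    return genome.get_gene("Tsyn0001")
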