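import pytest

from islekit.cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale recent-transfer cohort reused across test modules."""
    return simulate_cohort(
        CohortConfig(
            seed=101,
            genome_length=60_000,
            n_genes=40,
            island_length=9_000,
            island_genes=8,
        )
    )


@pytest.fixture(scope="session")
def small_proteomes(small_cohort):
    from islekit.orthology import proteome_from_genome

    return {g: proteome_from_genome(G) for g, G in small_cohort.genomes.items()}
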